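"""Developmental schedules, time frames and the synchronic expectation.

A staging table gives, per species, the onset of each character in thermal
time (degree-Celsius-days, °C·d). Normalizing by the span between
fecundation (the 0% boundary) and a fixed reference event (the 100%
boundary) puts all species on a common percent-of-development axis, on
which time landmarks (e.g. 25%, 50%, 75%) slice each species into OTUs.

If all species shared the same relative onset timing ("synchronic"
development), the OTUs would nest into a fixed pectinate hierarchy — the
expectation tree built by :func:`synchronic_tree`; departures from it are
heterochronies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .matrix_io import (
    ABSENT,
    PRESENT,
    UNKNOWN,
    CharacterDef,
    CharacterMatrix,
    OTULabel,
    default_characters,
)
from .tree import Node, Tree


class TimeFrameError(ValueError):
    """Invalid frame definition or frame/matrix mismatch."""


@dataclass(frozen=True)
class TimeFrame:
    """An ordered set of interior landmark percentages.

    The 0% and 100% boundary landmarks are implied (``include_bounds``,
    default on): every analysis anchors on the organ-free start and on the
    fully scored reference endpoint of development.
    """

    interior: tuple[float, ...]
    include_bounds: bool = True

    def __init__(self, interior: Sequence[float], include_bounds: bool = True):
        vals = tuple(float(v) for v in interior)
        if any(not 0.0 < v < 100.0 for v in vals):
            raise TimeFrameError(f"interior landmarks must lie in (0, 100): {vals}")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise TimeFrameError(f"landmarks must be strictly increasing: {vals}")
        object.__setattr__(self, "interior", vals)
        object.__setattr__(self, "include_bounds", include_bounds)

    @property
    def landmarks(self) -> tuple[float, ...]:
        if self.include_bounds:
            return (0.0,) + self.interior + (100.0,)
        return self.interior

    def name(self) -> str:
        return "-".join(
            str(int(v)) if v.is_integer() else str(v) for v in self.interior
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name()


@dataclass(frozen=True)
class StagingSchedule:
    """Per-species character onsets in thermal time.

    ``onsets`` maps 1-based character index to onset in °C·d (``None`` for
    unavailable data); ``t0`` is the thermal time of fecundation and
    ``t100`` that of the 100% boundary event.
    """

    species: str
    onsets: Mapping[int, Optional[float]]
    t0: float
    t100: float

    def __post_init__(self) -> None:
        if self.t100 <= self.t0:
            raise TimeFrameError(
                f"{self.species}: degenerate span, t100 ({self.t100}) must "
                f"exceed t0 ({self.t0})"
            )
        bad = [c for c, t in self.onsets.items() if t is not None and t < self.t0]
        if bad:
            raise TimeFrameError(
                f"{self.species}: onsets before fecundation for characters {bad}"
            )


def normalize_schedule(s: StagingSchedule) -> dict[int, Optional[float]]:
    """Onsets as percent of development: 100 * (t - t0) / (t100 - t0).

    Unknown onsets stay ``None``; events after the 100% boundary map
    beyond 100 and are kept (they are simply absent at every landmark).
    """
    span = s.t100 - s.t0
    return {
        c: None if t is None else 100.0 * (t - s.t0) / span
        for c, t in s.onsets.items()
    }


def build_matrix_from_schedules(
    schedules: Sequence[StagingSchedule],
    frame: TimeFrame,
    characters: Optional[Sequence[CharacterDef]] = None,
) -> CharacterMatrix:
    """Slice normalized schedules at the frame landmarks into OTU rows.

    A character is present at landmark L when its normalized onset is
    <= L (closed boundary: an event scored "at 25%" is visible at the 25%
    landmark), absent when the onset is later, unknown when the onset is
    unavailable. 0% rows are all-absent by definition — development
    starts organ-free — so unknown onsets are still coded absent there.
    """
    if not schedules:
        raise TimeFrameError("no schedules given")
    if not frame.landmarks:
        raise TimeFrameError("empty time frame")
    char_indices = sorted(schedules[0].onsets)
    for s in schedules[1:]:
        if sorted(s.onsets) != char_indices:
            raise TimeFrameError(
                f"{s.species}: character set differs from {schedules[0].species}"
            )
    chars = (
        tuple(characters)
        if characters is not None
        else default_characters(len(char_indices))
    )
    otus: list[OTULabel] = []
    rows: list[str] = []
    for s in schedules:
        pct = normalize_schedule(s)
        for lm in frame.landmarks:
            cells = []
            for c in char_indices:
                p = pct[c]
                if lm == 0.0:
                    cells.append(ABSENT)
                elif p is None:
                    cells.append(UNKNOWN)
                else:
                    cells.append(PRESENT if p <= lm else ABSENT)
            otus.append(OTULabel(s.species, lm))
            rows.append("".join(cells))
    return CharacterMatrix(otus=tuple(otus), characters=chars, rows=tuple(rows))


def select_frame(m: CharacterMatrix, frame: TimeFrame) -> CharacterMatrix:
    """Subset a matrix to one frame's OTUs.

    Rows are returned species-major (species in order of first appearance,
    landmarks ascending); every requested (species, landmark) must exist.
    """
    wanted: list[OTULabel] = []
    missing: list[str] = []
    for sp in m.species():
        for lm in frame.landmarks:
            otu = OTULabel(sp, lm)
            try:
                m.index_of(otu)
                wanted.append(otu)
            except KeyError:
                missing.append(otu.label)
    if missing:
        raise TimeFrameError(
            f"frame {frame.name()} requests OTUs absent from the matrix: "
            + ", ".join(missing[:6])
        )
    return m.subset(wanted)


def synchronic_tree(species: Sequence[str], frame: TimeFrame) -> Tree:
    """The pectinate hierarchy expected under synchronic development.

    Each landmark contributes one node holding every species' OTU at that
    landmark (a polytomy for three or more species) plus the node of the
    next landmark; the root holds the 0% OTUs and the innermost node the
    100% ones. Observed trees that deviate from this caterpillar reveal
    heterochronies.
    """
    if not species:
        raise TimeFrameError("no species given")
    landmarks = frame.landmarks
    if not landmarks:
        raise TimeFrameError("empty time frame")
    root = Node(None, [Node(OTULabel(sp, landmarks[0]).label) for sp in species])
    cursor = root
    for lm in landmarks[1:]:
        nxt = Node(None, [Node(OTULabel(sp, lm).label) for sp in species])
        cursor.add(nxt)
        cursor = nxt
    return Tree(root)
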