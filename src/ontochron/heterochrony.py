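"""Heterochrony detection: species late or advanced at a time landmark.

Two complementary screens are exposed and both appear, labelled, in the
report:

* set-based (``strict`` / ``majority``): a transparent matrix-only
  comparison of one species' states against the other species at the same
  landmark;
* tree-based (``tree``): reads the ACCTRAN character-change map on the
  consensus of the most parsimonious trees — a species is late when a
  character's gain subtends every other species' OTU at a landmark but
  not the focal one, advanced when the gain clusters the focal OTU with
  only later OTUs of the other species.

The two views can disagree on single characters when missing data or
homoplasy make the tree placement of a gain ambiguous; reporting both
keeps the evidence auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .consensus import strict_consensus
from .matrix_io import ABSENT, PRESENT, CharacterMatrix, OTULabel
from .parsimony import (
    CharacterChange,
    SearchOptions,
    SearchResult,
    acctran_changes,
    branch_and_bound_search,
)
from .timeframe import TimeFrame, select_frame
from .tree import Tree

Direction = Literal["late", "advanced"]
Mode = Literal["strict", "majority", "tree"]


class HeterochronyError(ValueError):
    """Invalid detection request (lone species, missing OTU, ...)."""


@dataclass(frozen=True)
class HeterochronyEvent:
    """One detected timing shift: ``species`` is ``direction`` at
    ``landmark``, diagnosed by ``characters`` under detection ``mode``."""

    species: str
    landmark: float
    direction: Direction
    characters: frozenset[int]
    mode: Mode

    def sort_key(self):
        return (self.landmark, self.species, self.direction, self.mode)


def _landmark_states(m: CharacterMatrix, landmark: float) -> dict[str, str]:
    """Species -> state row at one landmark."""
    return {
        o.species: r for o, r in zip(m.otus, m.rows) if o.landmark == landmark
    }


def _set_screen(m: CharacterMatrix, species: str, landmark: float,
                mode: str, direction: Direction) -> set[int]:
    if mode not in ("strict", "majority"):
        raise HeterochronyError(f"unknown set-screen mode {mode!r}")
    rows = _landmark_states(m, landmark)
    if species not in rows:
        raise HeterochronyError(f"{OTULabel(species, landmark).label} not in matrix")
    others = {sp: r for sp, r in rows.items() if sp != species}
    if not others:
        raise HeterochronyError(
            f"no other species at landmark {landmark}: nothing to compare against"
        )
    focal = rows[species]
    focal_state, other_state = (
        (ABSENT, PRESENT) if direction == "late" else (PRESENT, ABSENT)
    )
    out: set[int] = set()
    for j in range(m.n_characters):
        if focal[j] != focal_state:
            continue
        definite = [r[j] for r in others.values() if r[j] in (ABSENT, PRESENT)]
        agreeing = sum(1 for s in definite if s == other_state)
        if mode == "strict":
            if definite and agreeing == len(others) == len(definite):
                out.add(j + 1)
        else:
            if definite and agreeing * 2 > len(definite):
                out.add(j + 1)
    return out


def late_set(m: CharacterMatrix, species: str, landmark: float,
             mode: str = "strict") -> set[int]:
    """Characters the focal species still lacks at a landmark while the
    other species already show them.

    ``strict``: every other species is definitely present (unknowns
    disqualify a character). ``majority``: more than half of the other
    species with definite states are present; unknowns abstain.
    """
    return _set_screen(m, species, landmark, mode, "late")


def advanced_set(m: CharacterMatrix, species: str, landmark: float,
                 mode: str = "strict") -> set[int]:
    """Characters the focal species already shows at a landmark while the
    other species still lack them (modes as in :func:`late_set`)."""
    return _set_screen(m, species, landmark, mode, "advanced")


def tree_diagnostics(
    consensus: Tree,
    changes: dict[int, list[CharacterChange]],
    frame: TimeFrame,
) -> list[HeterochronyEvent]:
    """Read heterochronies off ACCTRAN gains mapped on a consensus tree.

    ``changes`` must be the change map computed on ``consensus`` itself
    (keys are node ids). For each character gain on the branch above a
    node N and each (species s, landmark L): s is *late* at L when every
    other species' L-OTU descends from N but s's does not; s is
    *advanced* at L when its L-OTU descends from N and every other
    species enters N's clade only after L.
    """
    nodes = {id(n): n for n in consensus.preorder()}
    if any(k not in nodes for k in changes):
        raise HeterochronyError("change map does not belong to this tree")
    below: dict[int, set[OTULabel]] = {}
    for n in consensus.root.postorder():
        if n.is_leaf and n.label is not None and n.label != consensus.root.label:
            below[id(n)] = {OTULabel.parse(n.label)}
        else:
            below[id(n)] = set().union(*(below[id(c)] for c in n.children), set())
    all_otus = below[id(consensus.root)]
    species = sorted({o.species for o in all_otus})
    landmarks = [lm for lm in frame.landmarks if lm > 0.0]
    found: dict[tuple[str, float, Direction], set[int]] = {}
    for node_id, chs in changes.items():
        gains = [c.char_index for c in chs if c.kind == "gain"]
        if not gains:
            continue
        clade = below[node_id]
        entry = {
            sp: min((o.landmark for o in clade if o.species == sp), default=None)
            for sp in species
        }
        for lm in landmarks:
            for sp in species:
                if OTULabel(sp, lm) not in all_otus:
                    continue
                others = [s2 for s2 in species if s2 != sp
                          and OTULabel(s2, lm) in all_otus]
                if not others:
                    continue
                focal_in = OTULabel(sp, lm) in clade
                if (not focal_in
                        and all(OTULabel(s2, lm) in clade for s2 in others)):
                    found.setdefault((sp, lm, "late"), set()).update(gains)
                elif (focal_in
                        and all(entry[s2] is None or entry[s2] > lm
                                for s2 in others)):
                    found.setdefault((sp, lm, "advanced"), set()).update(gains)
    events = [
        HeterochronyEvent(sp, lm, direction, frozenset(chars), "tree")
        for (sp, lm, direction), chars in found.items()
    ]
    return sorted(events, key=HeterochronyEvent.sort_key)


@dataclass
class HeterochronyReport:
    """One frame's full analysis: search summary plus detected events."""

    frame: TimeFrame
    best_length: int
    n_trees: int
    ci: float
    ri: float
    reported_ci: float
    reported_ri: float
    consensus: Tree
    events: list[HeterochronyEvent]

    def to_dict(self) -> dict:
        return {
            "frame": self.frame.name(),
            "best_length": self.best_length,
            "n_trees": self.n_trees,
            "ci": self.ci,
            "ri": self.ri,
            "reported_ci": self.reported_ci,
            "reported_ri": self.reported_ri,
            "events": [
                {
                    "species": e.species,
                    "landmark": e.landmark,
                    "direction": e.direction,
                    "characters": sorted(e.characters),
                    "mode": e.mode,
                }
                for e in self.events
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_markdown(self) -> str:
        lines = [
            f"## Frame {self.frame.name()}",
            "",
            f"- best length: {self.best_length} steps, "
            f"{self.n_trees} most parsimonious tree(s)",
            f"- CI {self.reported_ci:.2f} (full {self.ci:.4f}), "
            f"RI {self.reported_ri:.2f} (full {self.ri:.4f})",
            "",
        ]
        if not self.events:
            lines.append("No heterochronies detected.")
        for e in self.events:
            chars = ", ".join(str(c) for c in sorted(e.characters))
            lines.append(
                f"- [{e.mode}] {e.species} is {e.direction} at "
                f"{e.landmark:g}% (characters {chars})"
            )
        return "\n".join(lines)


def analyze_frame(m: CharacterMatrix, frame: TimeFrame,
                  opts: Optional[SearchOptions] = None) -> HeterochronyReport:
    """Run one frame end to end: subset, search, consensus, diagnostics."""
    opts = opts or SearchOptions()
    mf = select_frame(m, frame)
    result: SearchResult = branch_and_bound_search(mf, opts)
    cons = strict_consensus(result.trees)
    changes = acctran_changes(cons, mf)
    events: list[HeterochronyEvent] = list(tree_diagnostics(cons, changes, frame))
    for lm in frame.interior:
        present = {o.species for o in mf.otus if o.landmark == lm}
        for sp in sorted(present):
            if len(present) < 2:
                continue
            for mode in ("strict", "majority"):
                for direction, screen in (("late", late_set),
                                          ("advanced", advanced_set)):
                    chars = screen(mf, sp, lm, mode)
                    if chars:
                        events.append(HeterochronyEvent(
                            sp, lm, direction, frozenset(chars), mode))
    events.sort(key=HeterochronyEvent.sort_key)
    fit = result.fit
    return HeterochronyReport(
        frame=frame, best_length=result.best_length, n_trees=result.n_trees,
        ci=fit.ci, ri=fit.ri, reported_ci=fit.reported_ci,
        reported_ri=fit.reported_ri, consensus=cons, events=events,
    )


def run_pipeline(m: CharacterMatrix, frames: Sequence[TimeFrame],
                 opts: Optional[SearchOptions] = None
                 ) -> list[HeterochronyReport]:
    """Analyze several time frames of one matrix; deterministic for fixed
    options. Errors are annotated with the offending frame."""
    reports = []
    for frame in frames:
        try:
            reports.append(analyze_frame(m, frame, opts))
        except Exception as exc:
            raise type(exc)(f"frame {frame.name()}: {exc}") from exc
    return reports
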