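"""Binary presence/absence character matrices over developmental-time OTUs.

An OTU (operational taxonomic unit) here is a species considered at a given
landmark of its normalized developmental time, e.g. ``Tinca_tinca_25%``.
Rows are OTUs, columns are anatomical characters (organs or developmental
events) coded present (``1``), absent (``0``) or unavailable (``?``).

The module bundles a transcription-checked fixture: the 32-OTU x 53-character
matrix of early development for four freshwater teleosts (*Barbus barbus*,
*Tinca tinca*, *Hucho hucho*, *Thymallus thymallus*) together with the list
of character names, which drives the worked analyses elsewhere in the
package.
"""

from __future__ import annotations

import hashlib
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

PRESENT = "1"
ABSENT = "0"
UNKNOWN = "?"
STATE_SYMBOLS = frozenset({PRESENT, ABSENT, UNKNOWN})


class MatrixError(ValueError):
    """Base class for matrix construction and parsing problems."""


class MatrixDimensionError(MatrixError):
    """Rows of unequal length, or empty matrix where one is required."""


class MatrixStateError(MatrixError):
    """A cell holds a symbol outside {0, 1, ?}."""


class DuplicateLabelError(MatrixError):
    """Two rows share the same (species, landmark) label."""


@dataclass(frozen=True)
class CharacterDef:
    """A named character column, indexed 1..K."""

    index: int
    name: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise MatrixError(f"character index must be >= 1, got {self.index}")
        if not self.name:
            raise MatrixError("character name must be non-empty")


def default_characters(k: int) -> tuple[CharacterDef, ...]:
    """Placeholder definitions C1..Ck used when no character list is given."""
    return tuple(CharacterDef(i, f"C{i}") for i in range(1, k + 1))


def _format_landmark(value: float) -> str:
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


@dataclass(frozen=True, order=True)
class OTULabel:
    """A species observed at a landmark percentage of its development."""

    species: str
    landmark: float

    @property
    def label(self) -> str:
        return f"{self.species}_{_format_landmark(self.landmark)}%"

    @classmethod
    def parse(cls, text: str) -> "OTULabel":
        """Parse ``Genus_species_P%`` (the trailing ``%`` is optional).

        The species name may itself contain underscores; the final
        underscore-separated token is the landmark percentage.
        """
        tokens = text.strip().split("_")
        if len(tokens) < 2:
            raise MatrixError(f"cannot parse OTU label {text!r}: no landmark token")
        tail = tokens[-1].rstrip("%")
        try:
            landmark = float(tail)
        except ValueError:
            raise MatrixError(
                f"cannot parse OTU label {text!r}: landmark token {tokens[-1]!r} "
                "is not a percentage"
            ) from None
        if not 0.0 <= landmark <= 200.0:
            raise MatrixError(f"landmark {landmark} out of range in label {text!r}")
        return cls(species="_".join(tokens[:-1]), landmark=landmark)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class ValidationIssue:
    """One problem found by :func:`validate_matrix` (row/col are 0-based; -1 = n/a)."""

    kind: str
    row: int
    col: int
    message: str


@dataclass(frozen=True)
class CharacterMatrix:
    """Immutable OTU x character grid of presence states.

    ``rows[i]`` is the state string of ``otus[i]`` over the symbols
    ``0`` (absent), ``1`` (present) and ``?`` (unavailable). Subsetting
    operations return new matrices; the grid is never mutated in place.
    """

    otus: tuple[OTULabel, ...]
    characters: tuple[CharacterDef, ...]
    rows: tuple[str, ...]

    # -- basic geometry -------------------------------------------------
    @property
    def n_otus(self) -> int:
        return len(self.otus)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def labels(self) -> tuple[str, ...]:
        return tuple(o.label for o in self.otus)

    def species(self) -> tuple[str, ...]:
        """Species in order of first appearance."""
        seen: dict[str, None] = {}
        for o in self.otus:
            seen.setdefault(o.species, None)
        return tuple(seen)

    def landmarks(self) -> tuple[float, ...]:
        return tuple(sorted({o.landmark for o in self.otus}))

    # -- access ---------------------------------------------------------
    def state(self, row: int, char_index: int) -> str:
        """State of row ``row`` (0-based) at character ``char_index`` (1-based)."""
        return self.rows[row][char_index - 1]

    def column(self, char_index: int) -> str:
        """The state string of one character (1-based index) across all OTUs."""
        j = char_index - 1
        return "".join(r[j] for r in self.rows)

    def index_of(self, otu: OTULabel | str) -> int:
        if isinstance(otu, str):
            otu = OTULabel.parse(otu)
        try:
            return self.otus.index(otu)
        except ValueError:
            raise KeyError(f"OTU {otu.label} not in matrix") from None

    def row_of(self, otu: OTULabel | str) -> str:
        return self.rows[self.index_of(otu)]

    def subset(self, otus: Sequence[OTULabel]) -> "CharacterMatrix":
        """New matrix restricted to ``otus`` in the given order."""
        idx = [self.index_of(o) for o in otus]
        return CharacterMatrix(
            otus=tuple(self.otus[i] for i in idx),
            characters=self.characters,
            rows=tuple(self.rows[i] for i in idx),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [list(r) for r in self.rows],
            index=list(self.labels()),
            columns=[c.index for c in self.characters],
        )

    def checksum(self) -> str:
        """SHA-256 over the canonical text serialization of the grid."""
        payload = "\n".join(f"{o.label} {r}" for o, r in zip(self.otus, self.rows))
        return hashlib.sha256(payload.encode()).hexdigest()


def validate_matrix(m: CharacterMatrix) -> list[ValidationIssue]:
    """Report structural problems; an empty list means the matrix is valid."""
    issues: list[ValidationIssue] = []
    k = m.n_characters
    if len(m.rows) != len(m.otus):
        issues.append(
            ValidationIssue(
                "dimension", -1, -1,
                f"{len(m.rows)} state rows for {len(m.otus)} OTU labels",
            )
        )
    for i, row in enumerate(m.rows):
        if len(row) != k:
            issues.append(
                ValidationIssue(
                    "dimension", i, -1,
                    f"row {i} has {len(row)} states, expected {k}",
                )
            )
        for j, s in enumerate(row):
            if s not in STATE_SYMBOLS:
                issues.append(
                    ValidationIssue(
                        "state", i, j, f"illegal state symbol {s!r} at ({i}, {j})"
                    )
                )
    seen: dict[OTULabel, int] = {}
    for i, o in enumerate(m.otus):
        if o in seen:
            issues.append(
                ValidationIssue(
                    "uniqueness", i, -1,
                    f"duplicate OTU label {o.label} (rows {seen[o]} and {i})",
                )
            )
        else:
            seen[o] = i
    indices = [c.index for c in m.characters]
    if indices != list(range(1, k + 1)):
        issues.append(
            ValidationIssue(
                "characters", -1, -1,
                "character indices are not contiguous from 1",
            )
        )
    return issues


def _raise_issues(issues: list[ValidationIssue]) -> None:
    if not issues:
        return
    first = issues[0]
    exc = {
        "dimension": MatrixDimensionError,
        "state": MatrixStateError,
        "uniqueness": DuplicateLabelError,
    }.get(first.kind, MatrixError)
    raise exc("; ".join(i.message for i in issues))


def parse_matrix_text(
    text: str, characters: Optional[Sequence[CharacterDef]] = None
) -> CharacterMatrix:
    """Parse the simple text dialect: one ``label states`` pair per line.

    Each non-blank line holds an OTU label (``Genus_species_P%``) and a
    contiguous string over ``0``/``1``/``?``, separated by whitespace.
    """
    otus: list[OTULabel] = []
    rows: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise MatrixError(
                f"line {lineno}: expected 'label states', got {len(parts)} fields"
            )
        otus.append(OTULabel.parse(parts[0]))
        rows.append(parts[1])
    if not rows:
        raise MatrixDimensionError("no matrix rows found")
    k = len(rows[0])
    chars = tuple(characters) if characters is not None else default_characters(k)
    if len(chars) != k:
        raise MatrixDimensionError(
            f"{len(chars)} character definitions for {k} matrix columns"
        )
    m = CharacterMatrix(otus=tuple(otus), characters=chars, rows=tuple(rows))
    _raise_issues(validate_matrix(m))
    return m


# -- NEXUS interchange ---------------------------------------------------

_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.]+$")


def _nexus_quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_nexus(m: CharacterMatrix) -> str:
    """Serialize as a NEXUS DATA block (SYMBOLS="01", MISSING=?)."""
    if m.n_otus == 0 or m.n_characters == 0:
        raise MatrixDimensionError("cannot write an empty matrix to NEXUS")
    width = max(len(_nexus_quote(lbl)) for lbl in m.labels()) + 2
    out = io.StringIO()
    out.write("#NEXUS\n\nBEGIN DATA;\n")
    out.write(f"    DIMENSIONS NTAX={m.n_otus} NCHAR={m.n_characters};\n")
    out.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
    out.write("    MATRIX\n")
    for lbl, row in zip(m.labels(), m.rows):
        out.write(f"        {_nexus_quote(lbl):<{width}}{row}\n")
    out.write("    ;\nEND;\n")
    return out.getvalue()


def parse_nexus(
    text: str, characters: Optional[Sequence[CharacterDef]] = None
) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block (via dendropy) into a matrix."""
    import dendropy

    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises various DataError subclasses
        raise MatrixError(f"NEXUS parse failed: {exc}") from exc
    otus: list[OTULabel] = []
    rows: list[str] = []
    for taxon in dmat.taxon_namespace:
        seq = dmat[taxon]
        otus.append(OTULabel.parse(taxon.label))
        rows.append("".join(str(cell) for cell in seq.symbols_as_list()))
    if not rows:
        raise MatrixDimensionError("NEXUS file holds no matrix rows")
    k = len(rows[0])
    chars = tuple(characters) if characters is not None else default_characters(k)
    m = CharacterMatrix(otus=tuple(otus), characters=chars, rows=tuple(rows))
    _raise_issues(validate_matrix(m))
    return m


# -- CSV interchange -----------------------------------------------------

def write_csv(m: CharacterMatrix) -> str:
    return m.to_dataframe().to_csv(index_label="otu")


def parse_csv(
    text: str, characters: Optional[Sequence[CharacterDef]] = None
) -> CharacterMatrix:
    df = pd.read_csv(io.StringIO(text), index_col=0, dtype=str)
    otus = tuple(OTULabel.parse(lbl) for lbl in df.index)
    rows = tuple("".join(r) for r in df.to_numpy())
    chars = (
        tuple(characters)
        if characters is not None
        else default_characters(df.shape[1])
    )
    m = CharacterMatrix(otus=otus, characters=chars, rows=rows)
    _raise_issues(validate_matrix(m))
    return m


# -- bundled fixture -----------------------------------------------------

def load_character_names() -> tuple[CharacterDef, ...]:
    """The bundled list of 53 developmental character names."""
    raw = resources.files("ontochron.data").joinpath("characters.tsv").read_text()
    df = pd.read_csv(io.StringIO(raw), sep="\t")
    return tuple(CharacterDef(int(r["index"]), str(r["name"])) for _, r in df.iterrows())


def load_fixture_table1() -> CharacterMatrix:
    """The bundled 32-OTU x 53-character fish-development matrix.

    Four species (*Barbus barbus*, *Tinca tinca*, *Hucho hucho*,
    *Thymallus thymallus*) scored for organ presence at landmarks
    0/5/10/20/25/50/75/100% of normalized developmental time
    (degree-Celsius-days from fecundation to pectoral fin-ray onset).
    Character 23 (hatching glands) is unavailable for every non-zero
    *Barbus* OTU and is retained as ``?``, never imputed.
    """
    raw = resources.files("ontochron.data").joinpath("table1.txt").read_text()
    return parse_matrix_text(raw, characters=load_character_names())
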