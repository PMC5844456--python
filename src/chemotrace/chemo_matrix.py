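"""Compound-detection tables and their conversion to phylogenetic characters.

The raw observations are taxon x compound grids of five-valued detection
states (detected / not detected / partial / inconclusive / missing), the
machine-readable form of published scent-gland screening tables.  A
:class:`CodingPolicy` collapses groups of compound columns (e.g. all
naphthoquinone-family compounds) into binary presence/absence characters
suitable for parsimony mapping on a phylogeny.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    CharacterLookupError,
    ConfigurationError,
    DataFormatError,
    RankLookupError,
)

__all__ = [
    "DetectionState",
    "CompoundRecord",
    "Taxon",
    "DetectionMatrix",
    "CharacterMatrix",
    "CodingPolicy",
    "DEFAULT_POLICY",
    "POLICY_WITH_AQ",
    "load_compound_library",
    "load_lineages",
    "load_detection_table",
    "load_packaged_tables",
    "concat_matrices",
    "binarize",
    "summarize",
    "Summary",
]

_DATA = resources.files("chemotrace.data")

LINEAGE_RANKS = ("suborder", "superfamily", "family", "subfamily", "genus")


class DetectionState(str, enum.Enum):
    """Five-valued outcome of screening one compound in one taxon.

    Mirrors the symbols of published detection tables: filled square
    (detected), open square (not detected), half square (found in only part
    of the analysed individuals/species), question mark (no conclusive
    data), and dash (no data at all).
    """

    DETECTED = "detected"
    NOT_DETECTED = "not_detected"
    PARTIAL = "partial"
    INCONCLUSIVE = "inconclusive"
    MISSING = "missing"

    @property
    def positive(self) -> bool:
        return self in (DetectionState.DETECTED, DetectionState.PARTIAL)


#: CSV cell symbol -> state (unicode table symbols accepted as aliases).
CELL_SYMBOLS: dict[str, DetectionState] = {
    "D": DetectionState.DETECTED,
    "N": DetectionState.NOT_DETECTED,
    "P": DetectionState.PARTIAL,
    "I": DetectionState.INCONCLUSIVE,
    "M": DetectionState.MISSING,
    "■": DetectionState.DETECTED,      # filled square
    "□": DetectionState.NOT_DETECTED,  # open square
    "◩": DetectionState.PARTIAL,       # half-filled square
    "?": DetectionState.INCONCLUSIVE,
    "-": DetectionState.MISSING,
}


@dataclass(frozen=True)
class CompoundRecord:
    """One reference-library entry: a quinone and its GC-MS signature."""

    code: str
    name: str
    compound_class: str
    ri: float | None = None
    molecular_ion: int | None = None
    diagnostic_ions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.ri is not None and not self.ri > 0:
            raise ConfigurationError(f"{self.code}: retention index must be > 0")
        if list(self.diagnostic_ions) != sorted(self.diagnostic_ions, reverse=True):
            raise ConfigurationError(
                f"{self.code}: diagnostic ions must be sorted descending"
            )
        if self.molecular_ion is not None:
            bad = [m for m in self.diagnostic_ions if m >= self.molecular_ion + 2]
            if bad:
                raise ConfigurationError(
                    f"{self.code}: diagnostic ions {bad} exceed M+ + 1"
                )


@dataclass(frozen=True)
class Taxon:
    name: str
    lineage: Mapping[str, str] = field(default_factory=dict)

    def rank(self, rank: str) -> str | None:
        return self.lineage.get(rank) or None


def load_compound_library(path: str | Path | None = None) -> dict[str, CompoundRecord]:
    """Read a compound library CSV (defaults to the packaged quinone library).

    Columns: code, name, compound_class, ri, molecular_ion, diagnostic_ions
    (semicolon-joined m/z integers).
    """
    if path is None:
        text = (_DATA / "quinone_library.csv").read_text()
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    library: dict[str, CompoundRecord] = {}
    for row in rows:
        code = row["code"].strip()
        if code in library:
            raise ConfigurationError(f"duplicate compound code {code!r} in library")
        ions = tuple(
            int(tok) for tok in (row.get("diagnostic_ions") or "").split(";") if tok
        )
        library[code] = CompoundRecord(
            code=code,
            name=row.get("name", code),
            compound_class=row.get("compound_class", ""),
            ri=float(row["ri"]) if row.get("ri") else None,
            molecular_ion=int(row["molecular_ion"]) if row.get("molecular_ion") else None,
            diagnostic_ions=ions,
        )
    return library


def load_lineages(path: str | Path | None = None) -> dict[str, dict[str, str]]:
    """Read the sidecar CSV mapping taxon labels to rank values."""
    if path is None:
        text = (_DATA / "lineages.csv").read_text()
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    return {
        row["taxon"]: {r: row.get(r, "") for r in LINEAGE_RANKS} for row in rows
    }


class DetectionMatrix:
    """Rectangular taxa x compounds grid of :class:`DetectionState` cells."""

    def __init__(
        self,
        taxa: Sequence[Taxon],
        compounds: Sequence[str],
        cells: Mapping[tuple[str, str], DetectionState],
    ) -> None:
        names = [t.name for t in taxa]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DataFormatError(f"duplicate taxon rows: {dupes}")
        self.taxa = list(taxa)
        self.compounds = list(compounds)
        for t in self.taxa:
            for c in self.compounds:
                if (t.name, c) not in cells:
                    raise DataFormatError(f"missing cell ({t.name}, {c})")
        self._cells = dict(cells)

    def cell(self, taxon: str, compound: str) -> DetectionState:
        return self._cells[(taxon, compound)]

    @property
    def taxon_names(self) -> list[str]:
        return [t.name for t in self.taxa]

    def taxon(self, name: str) -> Taxon:
        for t in self.taxa:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            c: [self._cells[(t.name, c)].value for t in self.taxa]
            for c in self.compounds
        }
        return pd.DataFrame(data, index=self.taxon_names)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DetectionMatrix {len(self.taxa)} taxa x {len(self.compounds)} compounds>"


def _parse_rows(rows: list[list[str]], source: str) -> tuple[list[str], list[list[str]]]:
    if not rows or not any(any(cell.strip() for cell in r) for r in rows):
        raise DataFormatError(f"{source}: empty detection table")
    header, *body = rows
    if not body:
        raise DataFormatError(f"{source}: no taxon rows")
    return header, body


def load_detection_table(
    path: str | Path,
    library: Mapping[str, CompoundRecord],
    lineages: Mapping[str, Mapping[str, str]] | None = None,
) -> DetectionMatrix:
    """Load and validate a detection-table CSV.

    The header row is ``taxon`` followed by compound codes that must exist in
    *library*; every remaining cell must be one of the five detection-state
    symbols (D/N/P/I/M, or the original table symbols).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)]
    header, body = _parse_rows(rows, path.name)
    codes = [h.strip() for h in header[1:]]
    for col, code in enumerate(codes, start=2):
        if code not in library:
            raise DataFormatError(
                f"{path.name}: column {col} has unknown compound code {code!r}"
            )
    if lineages is None:
        lineages = load_lineages()
    taxa: list[Taxon] = []
    cells: dict[tuple[str, str], DetectionState] = {}
    for i, row in enumerate(body, start=2):
        if len(row) != len(codes) + 1:
            raise DataFormatError(
                f"{path.name}: row {i} has {len(row)} fields, expected {len(codes) + 1}"
            )
        name = row[0].strip()
        taxa.append(Taxon(name, dict(lineages.get(name, {}))))
        for code, raw in zip(codes, row[1:]):
            sym = raw.strip()
            if sym not in CELL_SYMBOLS:
                raise DataFormatError(
                    f"{path.name}: row {i} ({name}), compound {code}: "
                    f"invalid cell symbol {sym!r}"
                )
            cells[(name, code)] = CELL_SYMBOLS[sym]
    return DetectionMatrix(taxa, codes, cells)


def load_packaged_tables(
    which: Iterable[str] = ("eupnoi", "dyspnoi", "laniatores_cyphophthalmi"),
) -> DetectionMatrix:
    """Load and concatenate the packaged detection-table transcriptions."""
    library = load_compound_library()
    names = {
        "eupnoi": "eupnoi_detections.csv",
        "dyspnoi": "dyspnoi_detections.csv",
        "laniatores_cyphophthalmi": "laniatores_cyphophthalmi_detections.csv",
    }
    matrices = []
    for key in which:
        if key not in names:
            raise ConfigurationError(f"unknown packaged table {key!r}")
        with resources.as_file(_DATA / names[key]) as p:
            matrices.append(load_detection_table(p, library))
    return concat_matrices(matrices)


def concat_matrices(matrices: Sequence[DetectionMatrix]) -> DetectionMatrix:
    """Stack detection matrices sharing one compound set (row-wise)."""
    if not matrices:
        raise ConfigurationError("no matrices to concatenate")
    compounds = matrices[0].compounds
    for m in matrices[1:]:
        if m.compounds != compounds:
            raise ConfigurationError("matrices have differing compound columns")
    taxa: list[Taxon] = []
    cells: dict[tuple[str, str], DetectionState] = {}
    for m in matrices:
        taxa.extend(m.taxa)
        for t in m.taxa:
            for c in compounds:
                cells[(t.name, c)] = m.cell(t.name, c)
    return DetectionMatrix(taxa, compounds, cells)


# ---------------------------------------------------------------------------
# character coding


PRESENT, ABSENT, MISSING = "present", "absent", "missing"


@dataclass(frozen=True)
class CodingPolicy:
    """Named mapping from compound-column groups to binary characters.

    ``characters`` maps a character name to the compound codes that
    contribute to it.  For each taxon the collapse rule is evidence-based:
    any detected/partial cell makes the character present; otherwise any
    not-detected cell makes it absent; a group consisting solely of
    inconclusive/missing cells yields missing.
    """

    name: str
    characters: Mapping[str, tuple[str, ...]]

    def validate_against(self, matrix: DetectionMatrix) -> None:
        for char, codes in self.characters.items():
            unknown = [c for c in codes if c not in matrix.compounds]
            if unknown:
                raise ConfigurationError(
                    f"policy {self.name!r}, character {char!r}: compound codes "
                    f"{unknown} not in matrix"
                )


NQ_FAMILY = ("NQ", "MNQ", "MOQ", "MMOQ", "ND", "CNQ")
BQ_FAMILY = ("BQ", "ABQ")
AQ_FAMILY = ("MAQ", "DMAQ")

#: Default two-character coding: the naphthoquinone class (including the
#: diol and chloro derivatives) and the benzoquinone class.
DEFAULT_POLICY = CodingPolicy(
    "default", {"NQ-class": NQ_FAMILY, "BQ-class": BQ_FAMILY}
)

#: Optional extension with an anthraquinone character.
POLICY_WITH_AQ = CodingPolicy(
    "with-aq",
    {"NQ-class": NQ_FAMILY, "BQ-class": BQ_FAMILY, "AQ-class": AQ_FAMILY},
)


class CharacterMatrix:
    """Taxa x binary characters, cells in {present, absent, missing}."""

    def __init__(
        self,
        taxa: Sequence[str],
        characters: Sequence[str],
        states: Mapping[tuple[str, str], str],
        policy: str = "",
    ) -> None:
        self.taxa = list(taxa)
        self.characters = list(characters)
        for key, v in states.items():
            if v not in (PRESENT, ABSENT, MISSING):
                raise ConfigurationError(f"invalid character state {v!r} at {key}")
        self._states = dict(states)
        self.policy = policy

    def state(self, taxon: str, character: str) -> str:
        if character not in self.characters:
            raise CharacterLookupError(character)
        return self._states[(taxon, character)]

    def column(self, character: str) -> dict[str, str]:
        if character not in self.characters:
            raise CharacterLookupError(character)
        return {t: self._states[(t, character)] for t in self.taxa}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: [self._states[(t, c)] for t in self.taxa] for c in self.characters},
            index=self.taxa,
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "taxon"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CharacterMatrix":
        df = pd.read_csv(path, index_col=0, dtype=str)
        states = {
            (t, c): df.loc[t, c] for t in df.index for c in df.columns
        }
        return cls(list(df.index), list(df.columns), states)

    _SYMBOL = {PRESENT: "1", ABSENT: "0", MISSING: "?"}

    def to_nexus(self, path: str | Path) -> None:
        """Write a NEXUS CHARACTERS block (symbols 01, missing ?)."""
        width = max(len(t) for t in self.taxa) + 2
        lines = [
            "#NEXUS",
            "BEGIN TAXA;",
            f"    DIMENSIONS NTAX={len(self.taxa)};",
            "    TAXLABELS " + " ".join(self.taxa) + ";",
            "END;",
            "BEGIN CHARACTERS;",
            f"    DIMENSIONS NCHAR={len(self.characters)};",
            '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
            "    CHARSTATELABELS "
            + ", ".join(f"{i + 1} '{c}'" for i, c in enumerate(self.characters))
            + ";",
            "    MATRIX",
        ]
        for t in self.taxa:
            row = "".join(self._SYMBOL[self._states[(t, c)]] for c in self.characters)
            lines.append(f"    {t:<{width}}{row}")
        lines += ["    ;", "END;", ""]
        Path(path).write_text("\n".join(lines))


def binarize(
    matrix: DetectionMatrix, policy: CodingPolicy = DEFAULT_POLICY
) -> CharacterMatrix:
    """Collapse a detection matrix into binary characters under *policy*.

    Idempotent in the sense that the result depends only on the multiset of
    cells per (taxon, character group), so row/column permutation of the
    input never changes the output.
    """
    policy.validate_against(matrix)
    states: dict[tuple[str, str], str] = {}
    for t in matrix.taxa:
        for char, codes in policy.characters.items():
            group = [matrix.cell(t.name, c) for c in codes]
            if any(s.positive for s in group):
                states[(t.name, char)] = PRESENT
            elif any(s is DetectionState.NOT_DETECTED for s in group):
                states[(t.name, char)] = ABSENT
            else:
                states[(t.name, char)] = MISSING
    return CharacterMatrix(
        matrix.taxon_names, list(policy.characters), states, policy=policy.name
    )


# ---------------------------------------------------------------------------
# summaries


POSITIVE_STATES = (DetectionState.DETECTED, DetectionState.PARTIAL)


@dataclass
class Summary:
    """Counts of positive detections under a taxon/state filter."""

    n_taxa: int
    positive_compounds: list[str]
    taxa_per_compound: dict[str, int]

    @property
    def n_positive_compounds(self) -> int:
        return len(self.positive_compounds)


def summarize(
    matrix: DetectionMatrix,
    where: Mapping[str, str] | Callable[[Taxon], bool] | None = None,
    compounds: Sequence[str] | None = None,
    states: Sequence[DetectionState] = POSITIVE_STATES,
) -> Summary:
    """Count compounds with >= 1 positive cell and positive taxa per compound.

    *where* restricts the taxon rows, either as a ``{rank: value}`` mapping
    (a rank value absent from the data raises :class:`RankLookupError`) or
    an arbitrary predicate over :class:`Taxon`.
    """
    if compounds is None:
        compounds = matrix.compounds
    else:
        unknown = [c for c in compounds if c not in matrix.compounds]
        if unknown:
            raise RankLookupError(f"unknown compound codes {unknown}")
    states = tuple(DetectionState(s) for s in states)

    if where is None:
        keep = matrix.taxa
    elif callable(where):
        keep = [t for t in matrix.taxa if where(t)]
    else:
        for rank, value in where.items():
            if rank not in LINEAGE_RANKS:
                raise RankLookupError(f"unknown rank {rank!r}")
            if not any(t.rank(rank) == value for t in matrix.taxa):
                raise RankLookupError(f"no taxon with {rank}={value!r}")
        keep = [
            t
            for t in matrix.taxa
            if all(t.rank(rank) == value for rank, value in where.items())
        ]

    taxa_per_compound = {
        c: sum(1 for t in keep if matrix.cell(t.name, c) in states) for c in compounds
    }
    positive = [c for c in compounds if taxa_per_compound[c] > 0]
    return Summary(len(keep), positive, taxa_per_compound)
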