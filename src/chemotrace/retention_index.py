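"""Kovats retention indices and library-based peak identification.

On a GC run with a linear temperature programme, the retention index of a
compound eluting between the n0- and n1-carbon n-alkanes is obtained by
linear interpolation:

    RI = 100*n0 + 100*(n1 - n0) * (t_x - t_n0) / (t_n1 - t_n0)

which reduces to the familiar one-step formula when the ladder has no gaps
(n1 = n0 + 1).  Identification matches a peak's RI against a reference
library within a tolerance window and corroborates the hit by the fraction
of the peak's observed ions explained by the entry's diagnostic ions and
molecular ion (unit-mass resolution).
"""

from __future__ import annotations

import bisect
import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .chemo_matrix import CompoundRecord
from .errors import ConfigurationError, DataFormatError, RetentionIndexRangeError

__all__ = [
    "AlkaneLadder",
    "Peak",
    "Candidate",
    "kovats_ri",
    "identify",
    "annotate_peaks",
    "load_ladder",
    "load_peaks",
]


@dataclass(frozen=True)
class AlkaneLadder:
    """n-alkane calibration ladder: (carbon number, retention time/min)."""

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ConfigurationError("alkane ladder needs at least 2 entries")
        ns = [n for n, _ in self.entries]
        ts = [t for _, t in self.entries]
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ConfigurationError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ConfigurationError("retention times must be strictly increasing")

    @property
    def carbons(self) -> list[int]:
        return [n for n, _ in self.entries]

    @property
    def times(self) -> list[float]:
        return [t for _, t in self.entries]

    @property
    def span(self) -> tuple[float, float]:
        return self.entries[0][1], self.entries[-1][1]


@dataclass(frozen=True)
class Peak:
    """A detected chromatographic peak: retention time plus observed ions."""

    rt: float
    ions: tuple[int, ...] = ()
    peak_id: str = ""
    meta: Mapping[str, object] = field(default_factory=dict)


def kovats_ri(t_x: float, ladder: AlkaneLadder, extrapolate: bool = False) -> float:
    """Retention index of a compound eluting at *t_x* minutes.

    Exact at ladder points (RI of the Cn alkane is 100n) and invariant to
    affine rescaling of all retention times.  Outside the ladder span a
    :class:`RetentionIndexRangeError` is raised unless *extrapolate* is set,
    in which case the first/last segment is extended linearly (with a
    warning).
    """
    times = ladder.times
    lo, hi = ladder.span
    if t_x < lo or t_x > hi:
        if not extrapolate:
            raise RetentionIndexRangeError(
                f"t={t_x} min outside ladder span [{lo}, {hi}]"
            )
        warnings.warn(
            "retention time outside alkane ladder; extrapolating linearly",
            stacklevel=2,
        )
        i = 0 if t_x < lo else len(times) - 2
    else:
        # rightmost segment whose start is <= t_x
        i = min(bisect.bisect_right(times, t_x), len(times) - 1) - 1
        i = max(i, 0)
    n0, t0 = ladder.entries[i]
    n1, t1 = ladder.entries[i + 1]
    return 100.0 * n0 + 100.0 * (n1 - n0) * (t_x - t0) / (t1 - t0)


@dataclass(frozen=True)
class Candidate:
    """One ranked identification hit for a peak."""

    code: str
    name: str
    ri: float
    ri_distance: float
    ion_overlap: float


def _reference_ions(rec: CompoundRecord) -> frozenset[int]:
    ions = set(rec.diagnostic_ions)
    if rec.molecular_ion is not None:
        ions.add(rec.molecular_ion)
    return frozenset(ions)


def identify(
    peak: Peak,
    library: Mapping[str, CompoundRecord],
    ladder: AlkaneLadder | None = None,
    ri: float | None = None,
    ri_tol: float = 10.0,
    min_ion_frac: float = 0.5,
) -> list[Candidate]:
    """Rank library compounds compatible with a peak.

    The peak's RI is either passed directly (*ri*) or computed from its
    retention time via *ladder*.  A library entry is a candidate when its RI
    lies within *ri_tol* index units of the peak's and at least
    *min_ion_frac* of the peak's observed ions occur among the entry's
    diagnostic ions or molecular ion (integer m/z, unit resolution).
    Candidates are sorted by (RI distance, descending ion overlap, code), so
    ties are broken deterministically.
    """
    if not library:
        raise ConfigurationError("empty compound library")
    if ri_tol < 0:
        raise ConfigurationError("ri_tol must be >= 0")
    if not 0 < min_ion_frac <= 1:
        raise ConfigurationError("min_ion_frac must be in (0, 1]")
    if ri is None:
        if ladder is None:
            raise ConfigurationError("need either a precomputed RI or a ladder")
        ri = kovats_ri(peak.rt, ladder)
    observed = {int(round(m)) for m in peak.ions}
    hits: list[Candidate] = []
    for code in sorted(library):
        rec = library[code]
        if rec.ri is None:
            continue
        dist = abs(ri - rec.ri)
        if dist > ri_tol:
            continue
        reference = _reference_ions(rec)
        if observed:
            overlap = len(observed & reference) / len(observed)
        else:
            overlap = 0.0
        if overlap < min_ion_frac:
            continue
        hits.append(Candidate(code, rec.name, rec.ri, dist, overlap))
    hits.sort(key=lambda c: (c.ri_distance, -c.ion_overlap, c.code))
    return hits


# ---------------------------------------------------------------------------
# CSV plumbing


def load_ladder(path: str | Path) -> AlkaneLadder:
    """Read a ladder CSV with columns ``n`` (carbon number) and ``t`` (min)."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise DataFormatError(f"{Path(path).name}: empty ladder file")
    try:
        entries = tuple((int(r["n"]), float(r["t"])) for r in rows)
    except (KeyError, ValueError) as exc:
        raise DataFormatError(f"{Path(path).name}: bad ladder row ({exc})") from exc
    return AlkaneLadder(entries)


def load_peaks(path: str | Path) -> list[Peak]:
    """Read a peaks CSV: columns ``peak_id``, ``t``, ``ions`` (semicolon m/z)."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    peaks = []
    for i, r in enumerate(rows):
        try:
            ions = tuple(int(tok) for tok in (r.get("ions") or "").split(";") if tok)
            peaks.append(Peak(float(r["t"]), ions, r.get("peak_id") or f"peak{i + 1}"))
        except (KeyError, ValueError) as exc:
            raise DataFormatError(f"{Path(path).name}: bad peak row {i + 2} ({exc})") from exc
    return peaks


def annotate_peaks(
    peaks: Sequence[Peak],
    ladder: AlkaneLadder,
    library: Mapping[str, CompoundRecord],
    ri_tol: float = 10.0,
    min_ion_frac: float = 0.5,
) -> pd.DataFrame:
    """Annotate every peak against the library; one row per candidate.

    Peaks with no candidate get a single row with an empty code so that the
    output table still accounts for them.
    """
    records = []
    for peak in peaks:
        ri = kovats_ri(peak.rt, ladder)
        cands = identify(
            peak, library, ri=ri, ri_tol=ri_tol, min_ion_frac=min_ion_frac
        )
        if not cands:
            records.append(
                {"peak_id": peak.peak_id, "rt": peak.rt, "ri": round(ri, 1),
                 "rank": 0, "code": "", "ri_distance": float("nan"),
                 "ion_overlap": float("nan")}
            )
        for rank, c in enumerate(cands, start=1):
            records.append(
                {"peak_id": peak.peak_id, "rt": peak.rt, "ri": round(ri, 1),
                 "rank": rank, "code": c.code, "ri_distance": round(c.ri_distance, 2),
                 "ion_overlap": round(c.ion_overlap, 3)}
            )
    return pd.DataFrame.from_records(records)
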