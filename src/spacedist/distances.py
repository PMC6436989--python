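"""Kimura-corrected pairwise distances and distance matrices.

The mismatch fraction ``p`` observed at the don't-care columns of the
selected spaced-word matches is converted to an estimated number of
substitutions per site with Kimura's closed-form approximation of the PAM
distance,

    d = -ln(1 - p - 0.2 p**2),

the same correction protdist applies to alignment mismatch fractions.  The
formula saturates at the positive root of ``1 - p - 0.2 p**2 = 0``
(p ~ 0.8536); beyond it no finite distance exists.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .matching import MatchCollection, ScoringMatrix, Spamogram, blosum62, compare_proteomes
from .patterns import PatternSet
from .proteome import Proteome

__all__ = [
    "P_MAX",
    "DEFAULT_DISTANCE_CEILING",
    "SaturationError",
    "PairStatus",
    "kimura_distance",
    "PairwiseDistanceResult",
    "estimate_pair_distance",
    "DistanceMatrix",
    "build_distance_matrix",
    "write_phylip",
    "read_phylip",
]

#: positive root of 1 - p - 0.2 p^2 = 0; mismatch fractions at or above this
#: cannot be corrected (saturation)
P_MAX = (math.sqrt(1.8) - 1.0) / 0.4

#: distance assigned to pairs whose distance cannot be estimated
DEFAULT_DISTANCE_CEILING = 10.0


class SaturationError(ValueError):
    """Mismatch fraction at or beyond the saturation point of the correction."""


class PairStatus(str, Enum):
    OK = "ok"
    NO_MATCHES = "no_matches"
    SATURATED = "saturated"


def kimura_distance(p: float) -> float:
    """Kimura's approximate PAM distance from a mismatch fraction.

    Raises :class:`SaturationError` for ``p >= P_MAX`` and ``ValueError``
    for ``p`` outside [0, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"mismatch fraction must be in [0, 1], got {p}")
    arg = 1.0 - p - 0.2 * p * p
    if p >= P_MAX or arg <= 0.0:
        raise SaturationError(f"mismatch fraction {p} is at or beyond saturation ({P_MAX:.4f})")
    return -math.log(arg)


@dataclass(frozen=True)
class PairwiseDistanceResult:
    """Distance estimate for one taxon pair, with its evidence."""

    taxon1: str
    taxon2: str
    n_matches: int
    total_dontcare_columns: int
    total_mismatches: int
    p: float
    d: float
    status: PairStatus


def estimate_pair_distance(
    matches: MatchCollection,
    ceiling: float = DEFAULT_DISTANCE_CEILING,
) -> PairwiseDistanceResult:
    """Estimate the distance of one proteome pair from its selected matches.

    Mismatches and don't-care columns are pooled over all selected matches
    of all patterns before forming ``p``; pooling maximizes the effective
    column count behind a single estimate.  Pairs without matches or beyond
    saturation get the configured ceiling distance and a status flag.
    """
    t1, t2 = matches.prot1.taxon_name, matches.prot2.taxon_name
    n = matches.n_matches
    if n == 0:
        return PairwiseDistanceResult(t1, t2, 0, 0, 0, float("nan"), ceiling, PairStatus.NO_MATCHES)
    cols = matches.total_dontcare_columns
    mm = matches.total_mismatches
    p = mm / cols if cols else 0.0
    try:
        d = kimura_distance(p)
        status = PairStatus.OK
    except SaturationError:
        d = ceiling
        status = PairStatus.SATURATED
    return PairwiseDistanceResult(t1, t2, n, cols, mm, p, d, status)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair status flags."""

    names: tuple[str, ...]
    values: np.ndarray
    status: dict[tuple[str, str], PairStatus] = field(default_factory=dict)
    results: dict[tuple[str, str], PairwiseDistanceResult] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match name count")
        if len(set(self.names)) != n:
            raise ValueError("taxon names must be unique")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        self.values = v
        self.names = tuple(self.names)

    @property
    def n(self) -> int:
        return len(self.names)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.names.index(a), self.names.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.names), columns=list(self.names))


def build_distance_matrix(
    proteomes: Sequence[Proteome],
    pattern_set: PatternSet,
    matrix: ScoringMatrix | None = None,
    threshold: int = 0,
    ceiling: float = DEFAULT_DISTANCE_CEILING,
    spamogram_dir: str | Path | None = None,
) -> DistanceMatrix:
    """All pairwise distances among the given proteomes.

    Each unordered pair is compared exactly once; the matrix is symmetric by
    construction with a zero diagonal.  Optionally writes one spamogram TSV
    per pair.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    names = [p.taxon_name for p in proteomes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate taxon names")
    matrix = matrix or blosum62()

    n = len(proteomes)
    vals = np.zeros((n, n), dtype=float)
    status: dict[tuple[str, str], PairStatus] = {}
    results: dict[tuple[str, str], PairwiseDistanceResult] = {}
    for i, j in itertools.combinations(range(n), 2):
        mc, spam = compare_proteomes(proteomes[i], proteomes[j], pattern_set, matrix, threshold)
        res = estimate_pair_distance(mc, ceiling=ceiling)
        vals[i, j] = vals[j, i] = res.d
        key = (names[i], names[j])
        status[key] = res.status
        results[key] = res
        if spamogram_dir is not None:
            out = Path(spamogram_dir)
            out.mkdir(parents=True, exist_ok=True)
            spam.to_tsv(out / f"{names[i]}__{names[j]}.spamogram.tsv")
    return DistanceMatrix(tuple(names), vals, status, results)


def pair_report(dm: DistanceMatrix) -> pd.DataFrame:
    """Long-format per-pair report of the evidence behind each distance."""
    rows = [
        {
            "taxon1": r.taxon1,
            "taxon2": r.taxon2,
            "n_matches": r.n_matches,
            "columns": r.total_dontcare_columns,
            "mismatches": r.total_mismatches,
            "p": r.p,
            "d": r.d,
            "status": r.status.value,
        }
        for r in dm.results.values()
    ]
    return pd.DataFrame(rows)


def write_phylip(dm: DistanceMatrix, path: str | Path, strict: bool = False) -> None:
    """Write a square PHYLIP distance matrix (6-decimal rendering).

    Relaxed dialect by default (full names, two spaces before the row);
    ``strict=True`` pads/truncates names to 10 characters and refuses
    truncation collisions.
    """
    names = list(dm.names)
    if strict:
        short = [n[:10].ljust(10) for n in names]
        if len({s.strip() for s in short}) != len(short):
            raise ValueError("taxon name collision after strict 10-character truncation")
        names = short
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for name, row in zip(names, dm.values):
            fh.write(name + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Parse a square PHYLIP distance matrix (relaxed or strict names)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    if len(lines) != n + 1:
        raise ValueError(f"expected {n} matrix rows, found {len(lines) - 1}")
    names, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise ValueError("malformed PHYLIP row")
        names.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(tuple(names), np.asarray(rows))
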