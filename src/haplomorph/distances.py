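"""Pairwise genetic distances, the GD_min crosstable and threshold banding.

Sequence distances use pairwise deletion: each pair of sequences is compared
only at columns where both characters are unambiguous bases (A, C, G, T).
IUPAC ambiguity codes and gaps are treated as missing — phased haplotypes
should be unambiguous, so residual ambiguity signals upstream phasing noise
rather than a half-match.

The Kimura two-parameter (K2P) distance separates transitions (A<->G, C<->T;
proportion P) from transversions (proportion Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

It is undefined (saturated) when either log argument is <= 0; such pairs are
flagged, never silently dropped.

The GD_min crosstable reports, per pair of specimen units, the minimum
observed pairwise distance between their sequences (as %), banded against a
sister-species calibration window: a mean sister-species distance with 95%
confidence interval, deflated by a factor (default 0.80) because a minimum
over pairs is expected to sit ~20% below the between-species average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io import BandMatrix, HaplotypeAlignment, UnitAssignment

__all__ = [
    "DistanceMatrix",
    "GdBandConfig",
    "GdCrosstable",
    "UndefinedDistanceError",
    "k2p_distance",
    "p_distance",
    "pairwise_distance_matrix",
    "jaccard_distance_matrix",
    "gdmin_crosstable",
    "classify_gd",
    "count_species_conservative",
]

_BASES = set("ACGT")
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


class UndefinedDistanceError(ValueError):
    """No comparable columns, or the distance correction is saturated."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with labels; NaN flags undefined."""

    labels: list[str]
    D: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(np.nan_to_num(self.D), np.nan_to_num(self.D.T)):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        finite = self.D[np.isfinite(self.D)]
        if (finite < 0).any():
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.D[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)


def _comparable(a: str, b: str) -> tuple[list[str], list[str]]:
    pa, pb = [], []
    for x, y in zip(a.upper(), b.upper()):
        if x in _BASES and y in _BASES:
            pa.append(x)
            pb.append(y)
    return pa, pb


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatches over comparable (both-unambiguous) columns."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    pa, pb = _comparable(a, b)
    if not pa:
        raise UndefinedDistanceError("no comparable columns")
    return sum(x != y for x, y in zip(pa, pb)) / len(pa)


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance under pairwise deletion.

    Returns NaN when the correction is saturated (log argument <= 0);
    raises :class:`UndefinedDistanceError` when no columns are comparable.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    pa, pb = _comparable(a, b)
    n = len(pa)
    if n == 0:
        raise UndefinedDistanceError("no comparable columns")
    ts = tv = 0
    for x, y in zip(pa, pb):
        if x == y:
            continue
        if frozenset((x, y)) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def pairwise_distance_matrix(
    aln: HaplotypeAlignment, model: str = "k2p"
) -> DistanceMatrix:
    """All-pairs sequence distance matrix; saturated K2P pairs become NaN."""
    fn = {"k2p": k2p_distance, "p": p_distance}[model]
    n = len(aln.records)
    D = np.zeros((n, n))
    flagged = []
    for i, j in combinations(range(n), 2):
        d = fn(aln.records[i].sequence, aln.records[j].sequence)
        if np.isnan(d):
            flagged.append((aln.records[i].haplotype_id, aln.records[j].haplotype_id))
        D[i, j] = D[j, i] = d
    if flagged:
        warnings.warn(f"{len(flagged)} saturated/undefined {model} pairs flagged")
    return DistanceMatrix(
        labels=[r.haplotype_id for r in aln.records], D=D, metric_name=model
    )


def jaccard_distance_matrix(bands: BandMatrix) -> DistanceMatrix:
    """Jaccard distances over markers scored in both individuals.

    d(i, j) = 1 - |presence intersection| / |presence union|; a pair with an
    empty presence union is flagged NaN.
    """
    X = bands.values
    n = X.shape[0]
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        both = np.isfinite(X[i]) & np.isfinite(X[j])
        union = ((X[i] == 1) | (X[j] == 1)) & both
        inter = (X[i] == 1) & (X[j] == 1) & both
        if union.sum() == 0:
            D[i, j] = D[j, i] = float("nan")
        else:
            D[i, j] = D[j, i] = 1.0 - inter.sum() / union.sum()
    if np.isnan(D).any():
        warnings.warn("pairs with empty presence union flagged as undefined")
    return DistanceMatrix(labels=list(bands.individuals), D=D, metric_name="jaccard")


@dataclass
class GdBandConfig:
    """Sister-species calibration for banding GD_min values (all in %).

    Defaults: mean sister-species distance 3.98% with 95% CI [3.36, 4.59],
    deflated by 0.80 since the observed minimum sits below the average.
    """

    sister_mean: float = 3.98
    sister_ci: tuple[float, float] = (3.36, 4.59)
    gdmin_deflation: float = 0.80

    def __post_init__(self) -> None:
        lo, hi = self.sister_ci
        if not lo < self.sister_mean < hi:
            raise ValueError("sister CI must bracket the mean")
        if not 0.0 < self.gdmin_deflation <= 1.0:
            raise ValueError("deflation must be in (0, 1]")

    @property
    def window(self) -> tuple[float, float]:
        lo, hi = self.sister_ci
        return self.gdmin_deflation * lo, self.gdmin_deflation * hi


def classify_gd(gdmin_pct: float, cfg: GdBandConfig | None = None) -> str:
    """Band a GD_min percentage as intraspecific / sister / interspecific.

    The sister window is inclusive at both ends.
    """
    cfg = cfg or GdBandConfig()
    lo, hi = cfg.window
    if gdmin_pct < lo:
        return "intraspecific"
    if gdmin_pct <= hi:
        return "sister"
    return "interspecific"


@dataclass
class GdCrosstable:
    units: list[str]
    M: np.ndarray  # GD_min as %
    band: np.ndarray  # object array of labels
    config: GdBandConfig = field(default_factory=GdBandConfig)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.units, columns=self.units)

    def lower_triangle_csv(self) -> pd.DataFrame:
        """Lower-triangle layout, % rounded half-even to 1 decimal."""
        out = pd.DataFrame("", index=self.units, columns=self.units, dtype=object)
        for i in range(len(self.units)):
            for j in range(i + 1):
                v = self.M[i, j]
                out.iat[i, j] = "" if np.isnan(v) else f"{v:.1f}"
        return out


def gdmin_crosstable(
    dm: DistanceMatrix,
    units: UnitAssignment,
    cfg: GdBandConfig | None = None,
    include_hybrids: bool = True,
) -> GdCrosstable:
    """Minimum observed between-unit distance (%), banded per :func:`classify_gd`.

    Distance-matrix labels are haplotype ids; each maps to its individual's
    specimen unit. Hybrid units (code containing "x") are retained by default,
    mirroring a crosstable that keeps named hybrid units as explicit rows;
    pass ``include_hybrids=False`` to drop them. NaN-flagged pairs are
    skipped in the minimum (with a warning); a unit pair with only flagged
    distances gets a NaN cell.
    """
    from .io import split_haplotype_id

    cfg = cfg or GdBandConfig()
    unit_names = units.units()
    if not include_hybrids:
        unit_names = [u for u in unit_names if not UnitAssignment.is_hybrid(u)]
    members: dict[str, list[int]] = {u: [] for u in unit_names}
    for idx, label in enumerate(dm.labels):
        ind = label if label in units.unit_of else split_haplotype_id(label)[0]
        unit = units.unit_of.get(ind)
        if unit in members:
            members[unit].append(idx)
    empty = [u for u, rows in members.items() if not rows]
    if empty:
        raise ValueError(f"units with no sequences in the distance matrix: {empty}")
    if len(unit_names) < 2:
        raise ValueError("need at least 2 units")

    k = len(unit_names)
    M = np.zeros((k, k))
    skipped = 0
    for i, j in combinations(range(k), 2):
        block = dm.D[np.ix_(members[unit_names[i]], members[unit_names[j]])]
        finite = block[np.isfinite(block)]
        skipped += block.size - finite.size
        val = float("nan") if finite.size == 0 else 100.0 * finite.min()
        M[i, j] = M[j, i] = val
    if skipped:
        warnings.warn(f"{skipped} flagged distances skipped in GD_min minima")

    band = np.empty((k, k), dtype=object)
    band[:] = ""
    for i, j in combinations(range(k), 2):
        label = "undefined" if np.isnan(M[i, j]) else classify_gd(M[i, j], cfg)
        band[i, j] = band[j, i] = label
    return GdCrosstable(units=unit_names, M=M, band=band, config=cfg)


def count_species_conservative(
    ct: GdCrosstable, include_hybrids: bool = False
) -> int:
    """Conservative species count: single-linkage merge of intraspecific pairs.

    Units whose pairwise band is ``intraspecific`` are merged transitively;
    the count is the number of resulting components. Hybrid units are
    excluded by default — a named hybrid is not an extra species.
    """
    keep = [
        i
        for i, u in enumerate(ct.units)
        if include_hybrids or not UnitAssignment.is_hybrid(u)
    ]
    parent = {i: i for i in keep}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in combinations(keep, 2):
        if ct.band[i, j] == "intraspecific":
            parent[find(i)] = find(j)
    return len({find(i) for i in keep})
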