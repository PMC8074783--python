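"""Readers, writers and shared containers for the pipeline's external formats.

The pipeline consumes four kinds of external data: an aligned FASTA of phased
nuclear (ITS-type) haplotypes, a newick tree with node supports, a binary
dominant-marker (band presence/absence) matrix, and a morphology table with a
variable-metadata sheet plus a specimen-unit assignment table.

FASTA header convention for phased haplotypes
---------------------------------------------
A trailing lowercase letter on a header names a phased haplotype of one
individual: ``>626a`` and ``>626b`` are two haplotypes of individual ``626``.
A header without such a suffix is a single (homozygous-observed) haplotype.
Any number of haplotypes per individual is accepted; more than four triggers
a warning because direct Sanger phasing rarely resolves more.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTRYSWKMBDHVN-")

__all__ = [
    "HaplotypeRecord",
    "HaplotypeAlignment",
    "SupportTree",
    "BandMatrix",
    "MorphoTable",
    "UnitAssignment",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "read_band_matrix",
    "read_morphology",
    "read_unit_assignment",
    "read_tables",
]


class AlignmentError(ValueError):
    """Raised when sequences violate alignment invariants."""


@dataclass(frozen=True)
class HaplotypeRecord:
    """One phased haplotype sequence tied to the individual that carries it."""

    haplotype_id: str
    individual_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AlignmentError(f"empty sequence for record {self.haplotype_id!r}")
        bad = set(self.sequence.upper()) - IUPAC_DNA
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence.upper()) if c in bad
            )
            raise AlignmentError(
                f"illegal character {self.sequence[pos]!r} at position {pos} "
                f"in record {self.haplotype_id!r}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())


_SUFFIX_RE = re.compile(r"^(?P<ind>.*?[^a-z])(?P<suffix>[a-z])$")


def split_haplotype_id(haplotype_id: str) -> tuple[str, str | None]:
    """Split ``"626a"`` into ``("626", "a")``; no-suffix ids map to themselves."""
    m = _SUFFIX_RE.match(haplotype_id)
    if m:
        return m.group("ind"), m.group("suffix")
    return haplotype_id, None


@dataclass
class HaplotypeAlignment:
    """An aligned set of haplotype records of identical length."""

    records: list[HaplotypeRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentError("an alignment needs at least 2 records")
        ref = len(self.records[0].sequence)
        for rec in self.records[1:]:
            if len(rec.sequence) != ref:
                raise AlignmentError(
                    f"record {rec.haplotype_id!r} has length "
                    f"{len(rec.sequence)}, expected {ref}"
                )
        counts = self.haplotypes_per_individual()
        over = {k: v for k, v in counts.items() if v > 4}
        if over:
            warnings.warn(
                f"individuals with more than 4 haplotypes: {sorted(over)}",
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    def __len__(self) -> int:
        return len(self.records)

    def haplotypes_per_individual(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.individual_id] = counts.get(rec.individual_id, 0) + 1
        return counts

    def individuals(self) -> dict[str, list[HaplotypeRecord]]:
        out: dict[str, list[HaplotypeRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.individual_id, []).append(rec)
        return out

    def matrix(self) -> np.ndarray:
        """Return the alignment as a (records x columns) character array."""
        return np.array([list(r.sequence) for r in self.records])


@dataclass
class SupportTree:
    """Rooted tree with branch lengths (relative time) and node supports in [0, 1]."""

    tree: dendropy.Tree
    ultrametric_deviation: float = 0.0

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class BandMatrix:
    """Binary dominant-marker scores: individuals x markers, NaN = not scored."""

    individuals: list[str]
    markers: list[str]
    values: np.ndarray  # float array, entries 0.0 / 1.0 / NaN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.individuals), len(self.markers)):
            raise ValueError("band matrix shape does not match labels")
        finite = self.values[np.isfinite(self.values)]
        if not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("band values must be 0, 1 or missing")
        # A marker never observed present may be absence of amplification
        # rather than band absence; flag it, never drop it silently.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_any = np.nansum(self.values, axis=0)
        self.empty_markers = [
            m for m, s in zip(self.markers, col_any) if s == 0
        ]
        if self.empty_markers:
            warnings.warn(
                f"markers with no scored presence: {self.empty_markers}",
                stacklevel=2,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individuals, columns=self.markers)


VALID_KINDS = ("continuous", "ordinal", "binary")


@dataclass
class MorphoTable:
    """Accessions x mixed-type morphological variables (NaN = missing).

    ``kinds`` maps each variable to continuous / ordinal / binary. Ordinal
    values are averages of two independent scorings and therefore live on a
    half-integer grid.
    """

    accessions: list[str]
    variables: list[str]
    kinds: dict[str, str]
    values: np.ndarray
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.accessions), len(self.variables)):
            raise ValueError("morphology matrix shape does not match labels")
        for var in self.variables:
            kind = self.kinds.get(var)
            if kind not in VALID_KINDS:
                raise ValueError(f"unknown variable kind {kind!r} for {var!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accessions, columns=self.variables)

    def subset(self, variables: Iterable[str]) -> "MorphoTable":
        variables = list(variables)
        idx = [self.variables.index(v) for v in variables]
        return MorphoTable(
            accessions=list(self.accessions),
            variables=variables,
            kinds={v: self.kinds[v] for v in variables},
            values=self.values[:, idx],
            units={v: self.units.get(v, "") for v in variables},
        )


@dataclass
class UnitAssignment:
    """Maps individuals to specimen units and units to genetic main clusters.

    Specimen units are genotypically defined groups (phylogenetic cluster x
    haploweb field x dominant-marker subcluster), e.g. ``"2.5.1"``. Hybrid
    units carry an "x" between the parental unit codes (``"4.1.4x4.2.3"``).
    """

    unit_of: dict[str, str]
    cluster_of: dict[str, str] = field(default_factory=dict)
    region_of: dict[str, str] = field(default_factory=dict)

    def units(self) -> list[str]:
        return sorted(set(self.unit_of.values()))

    def members(self, unit: str) -> list[str]:
        return sorted(i for i, u in self.unit_of.items() if u == unit)

    @staticmethod
    def is_hybrid(unit: str) -> bool:
        return "x" in unit.lower() or "×" in unit

    def main_cluster(self, individual: str) -> str | None:
        unit = self.unit_of.get(individual)
        if unit is None:
            return None
        return self.cluster_of.get(unit, unit.split(".")[0])


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta(path: str | Path) -> HaplotypeAlignment:
    """Read an aligned FASTA into a :class:`HaplotypeAlignment`.

    Raises :class:`AlignmentError` naming the offending record on unequal
    lengths or illegal characters.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ind, _ = split_haplotype_id(rec.id)
        records.append(HaplotypeRecord(rec.id, ind, str(rec.seq)))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return HaplotypeAlignment(records)


def write_fasta(aln: HaplotypeAlignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.haplotype_id, description="")
        for r in aln.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_newick(path_or_string: str | Path) -> SupportTree:
    """Read a rooted newick tree whose internal node labels carry supports.

    Supports on a [0, 100] scale are rescaled to [0, 1]. The returned tree
    records the relative deviation from ultrametricity (max minus min
    root-to-tip distance over max).
    """
    text = str(path_or_string)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "Multiple occurrences" in msg:
            raise ValueError(f"duplicate leaf names: {msg}") from exc
        raise ValueError(msg) from exc
    names = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf names: {dupes}")

    supports = []
    for node in tree.preorder_internal_node_iter():
        if node.label is None or node.label == "":
            node.support = None
            continue
        try:
            val = float(node.label)
        except ValueError:
            raise ValueError(f"non-numeric node support label {node.label!r}")
        supports.append((node, val))
    raw = [v for _, v in supports]
    scale = 100.0 if raw and max(raw) > 1.0 else 1.0
    for node, val in supports:
        sup = val / scale
        if not 0.0 <= sup <= 1.0:
            raise ValueError(f"support {val} outside [0, 1] after rescaling")
        node.support = sup

    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    dmax = max(depths)
    deviation = 0.0 if dmax == 0 else (dmax - min(depths)) / dmax
    return SupportTree(tree=tree, ultrametric_deviation=deviation)


def read_band_matrix(path: str | Path) -> BandMatrix:
    df = pd.read_csv(path, index_col=0)
    return BandMatrix(
        individuals=[str(i) for i in df.index],
        markers=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def read_morphology(values_path: str | Path, meta_path: str | Path) -> MorphoTable:
    """Read a morphology table plus its variable-metadata sheet.

    The metadata CSV needs columns ``variable`` and ``kind``; an optional
    ``units`` column is carried through. Empty cells are missing, never 0.
    """
    df = pd.read_csv(values_path, index_col=0)
    meta = pd.read_csv(meta_path)
    kinds = dict(zip(meta["variable"].astype(str), meta["kind"].astype(str)))
    units = (
        dict(zip(meta["variable"].astype(str), meta["units"].astype(str)))
        if "units" in meta.columns
        else {}
    )
    unknown = [v for v in df.columns if v not in kinds]
    if unknown:
        raise ValueError(f"variables without declared kind: {unknown}")
    return MorphoTable(
        accessions=[str(i) for i in df.index],
        variables=[str(c) for c in df.columns],
        kinds=kinds,
        values=df.to_numpy(dtype=float),
        units=units,
    )


def read_unit_assignment(path: str | Path) -> UnitAssignment:
    """Read the individual -> specimen-unit table.

    Columns: ``individual``, ``unit``; optional ``main_cluster`` and
    ``region``.
    """
    df = pd.read_csv(path, dtype=str)
    unit_of = dict(zip(df["individual"], df["unit"]))
    cluster_of: dict[str, str] = {}
    region_of: dict[str, str] = {}
    if "main_cluster" in df.columns:
        cluster_of = {
            u: c
            for u, c in zip(df["unit"], df["main_cluster"])
            if isinstance(c, str) and c
        }
    if "region" in df.columns:
        region_of = {
            i: r
            for i, r in zip(df["individual"], df["region"])
            if isinstance(r, str) and r
        }
    return UnitAssignment(unit_of=unit_of, cluster_of=cluster_of, region_of=region_of)


def read_tables(
    bands_path: str | Path,
    morphology_path: str | Path,
    morphology_meta_path: str | Path,
    units_path: str | Path,
) -> tuple[BandMatrix, MorphoTable, UnitAssignment]:
    bands = read_band_matrix(bands_path)
    morpho = read_morphology(morphology_path, morphology_meta_path)
    units = read_unit_assignment(units_path)
    unassigned = [a for a in morpho.accessions if a not in units.unit_of]
    if unassigned:
        warnings.warn(
            "accessions in the morphology table without a unit assignment "
            f"(excluded from constrained analyses): {unassigned}",
            stacklevel=2,
        )
    return bands, morpho, units
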