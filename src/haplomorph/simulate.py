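"""Synthetic data with known truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* a species tree (Yule topology over K species, scaled to a between-species
  depth) with a Kingman coalescent subtree of haplotypes inside each species;
* haplotype sequences evolved under Jukes-Cantor from a random root — the
  estimator downstream is K2P, so estimation is deliberately exercised under
  mild model misspecification;
* diploid individuals drawing one or two haplotypes from their species pool,
  with a configurable fraction of inter-species hybrids drawing one
  haplotype from each of two species;
* cluster-structured dominant-marker band matrices (each marker has a home
  cluster where its band is frequent);
* unit-structured morphology with the mixed-type schema of a 122-variable
  matrix (59 continuous, 52 ordinal scored twice in half-steps, 11 binary),
  with hybrids placed at the parental midpoint and optional near-duplicate
  variables to exercise collinearity pruning.

Every generator consumes the config's seeded generator stream and is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io import (
    BandMatrix,
    HaplotypeAlignment,
    HaplotypeRecord,
    MorphoTable,
    SupportTree,
    UnitAssignment,
)

__all__ = [
    "SimConfig",
    "TruthTable",
    "simulate_species_tree",
    "simulate_haplotypes",
    "simulate_individuals",
    "simulate_bands",
    "simulate_morphology",
    "simulate_dataset",
]

_NUC = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Scenario parameters; defaults state a well-separated K-species world.

    ``depth_between``/``depth_within`` are expected substitutions per site;
    the 10:1 default ratio keeps species distinct but not trivially so.
    ``seq_len`` 690 and the 59/52/11 morphology split mirror the marker and
    trait schema the pipeline targets. ``effect_size`` is the typical
    between-unit mean shift in within-unit standard deviations.
    """

    K_species: int = 5
    depth_between: float = 0.06
    depth_within: float = 0.002
    seq_len: int = 690
    n_individuals_per_species: int = 6
    het_rate: float = 0.5
    hybrid_fraction: float = 0.0
    n_haplotypes_per_species: int = 4
    min_split_frac: float = 0.5
    n_markers: int = 30
    band_major: float = 0.9
    band_minor: float = 0.1
    n_cont: int = 59
    n_ord: int = 52
    n_bin: int = 11
    n_informative: int | None = 12
    n_duplicate: int = 3
    effect_size: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_species < 1:
            raise ValueError("K_species must be >= 1")
        for name in ("het_rate", "hybrid_fraction", "band_major", "band_minor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hybrid_fraction > 0 and self.K_species < 2:
            raise ValueError("hybrids need at least 2 species")
        if self.n_cont + self.n_ord + self.n_bin < 1:
            raise ValueError("at least one morphology variable required")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthTable:
    """Ground truth emitted alongside every simulated dataset."""

    species_of: dict[str, int] = field(default_factory=dict)  # individual -> species
    hybrid_parents: dict[str, tuple[int, int]] = field(default_factory=dict)
    haplotypes_of: dict[str, list[str]] = field(default_factory=dict)
    species_of_haplotype: dict[str, int] = field(default_factory=dict)
    unit_means: dict[str, np.ndarray] = field(default_factory=dict)

    def is_hybrid(self, individual: str) -> bool:
        return individual in self.hybrid_parents

    def unit_assignment(self) -> UnitAssignment:
        unit_of = {}
        for ind, sp in self.species_of.items():
            if ind in self.hybrid_parents:
                a, b = self.hybrid_parents[ind]
                unit_of[ind] = f"{a + 1}.0.0x{b + 1}.0.0"
            else:
                unit_of[ind] = f"{sp + 1}.0.0"
        cluster_of = {u: u.split(".")[0] for u in set(unit_of.values())}
        return UnitAssignment(unit_of=unit_of, cluster_of=cluster_of)


def _coalescent_times(n: int, scale: float, rng: np.random.Generator) -> list[float]:
    """Kingman coalescent event heights for n lineages, time scaled by
    ``scale`` (the expected depth is scale * (1 - 1/n) * 2 ... standard
    E[T_MRCA] = 2(1 - 1/n) in units of scale)."""
    t = 0.0
    times = []
    for k in range(n, 1, -1):
        t += rng.exponential(scale / (k * (k - 1) / 2.0))
        times.append(t)
    return times


def _yule_heights(k: int, rng: np.random.Generator, floor: float) -> list[float]:
    """Heights of the k-1 internal nodes of a Yule tree with k tips,
    normalized so the root sits at 1.

    The present is placed one further exponential wait after the last split,
    then heights are affinely mapped onto [floor, 1]: no species split is
    shallower than ``floor`` times the root depth, keeping every species
    pair genuinely diverged rather than mid-radiation.
    """
    if k == 1:
        return []
    t = 0.0
    split_times = []  # forward times of splits
    for n in range(1, k):
        t += rng.exponential(1.0 / n)
        split_times.append(t)
    present = t + rng.exponential(1.0 / k)
    heights = np.array([present - s for s in split_times])
    heights /= heights.max()
    if len(heights) > 1:
        lo = heights.min()
        if lo < floor and lo < 1.0:
            heights = floor + (heights - lo) * (1.0 - floor) / (1.0 - lo)
    return sorted(heights.tolist(), reverse=True)


def simulate_species_tree(cfg: SimConfig) -> tuple[SupportTree, dict[str, int]]:
    """Ultrametric tree: Yule over species scaled to ``depth_between``, a
    coalescent haplotype subtree of ``n_haplotypes_per_species`` tips inside
    each species at ``depth_within``. The small per-species haplotype pool
    means individuals share haplotypes, as real populations do. Supports are
    set to 1.0.

    Returns the tree and the species index of each haplotype leaf.
    """
    rng = cfg.rng()
    K = cfg.K_species
    n_hap = max(2, cfg.n_haplotypes_per_species)

    taxa = dendropy.TaxonNamespace()

    def coalescent_subtree(labels: list[str], scale: float) -> tuple[dendropy.Node, float]:
        nodes = []
        for lab in labels:
            taxon = taxa.new_taxon(label=lab)
            nd = dendropy.Node(taxon=taxon)
            nd.height = 0.0
            nodes.append(nd)
        heights = _coalescent_times(len(labels), scale, rng)
        for h in heights:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            parent = dendropy.Node()
            parent.height = h
            a, b = nodes[i], nodes[j]
            parent.add_child(a)
            parent.add_child(b)
            a.edge.length = h - a.height
            b.edge.length = h - b.height
            nodes = [n for k_, n in enumerate(nodes) if k_ not in (i, j)]
            nodes.append(parent)
        return nodes[0], (heights[-1] if heights else 0.0)

    species_of_haplotype: dict[str, int] = {}
    if K == 1:
        labels = [f"s1h{i + 1}" for i in range(n_hap)]
        species_of_haplotype.update({lab: 0 for lab in labels})
        root, _ = coalescent_subtree(labels, cfg.depth_within)
        root.edge.length = 0.0
        tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    else:
        sp_heights = [
            h * cfg.depth_between
            for h in _yule_heights(K, rng, cfg.min_split_frac)
        ]
        # build a random Yule topology by sequential random joins at the
        # recorded heights (equivalent in distribution to the Yule process)
        tips = []
        for s in range(K):
            labels = [f"s{s + 1}h{i + 1}" for i in range(n_hap)]
            species_of_haplotype.update({lab: s for lab in labels})
            sub, sub_h = coalescent_subtree(labels, cfg.depth_within)
            sub.height = sub_h
            tips.append(sub)
        pending = list(tips)
        for h in sorted(sp_heights):  # youngest join first
            i, j = sorted(rng.choice(len(pending), size=2, replace=False))
            parent = dendropy.Node()
            parent.height = max(h, pending[i].height, pending[j].height)
            a, b = pending[i], pending[j]
            parent.add_child(a)
            parent.add_child(b)
            a.edge.length = parent.height - a.height
            b.edge.length = parent.height - b.height
            pending = [n for k_, n in enumerate(pending) if k_ not in (i, j)]
            pending.append(parent)
        root = pending[0]
        root.edge.length = 0.0
        tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    for node in tree.preorder_internal_node_iter():
        node.support = 1.0
        node.label = "1.0"
    return SupportTree(tree=tree, ultrametric_deviation=0.0), species_of_haplotype


def simulate_haplotypes(
    tree: SupportTree, cfg: SimConfig, species_of_haplotype: dict[str, int] | None = None
) -> HaplotypeAlignment:
    """Jukes-Cantor evolution from a uniform-random root sequence.

    Substitution counts per branch are Poisson(branch_length * seq_len);
    each substitution hits a uniform site and switches it to one of the
    three other bases.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    root_seq = rng.integers(0, 4, size=cfg.seq_len)

    seqs: dict[str, np.ndarray] = {}

    def evolve(node, seq: np.ndarray) -> None:
        bl = node.edge.length or 0.0
        seq = seq.copy()
        n_sub = rng.poisson(bl * cfg.seq_len)
        for _ in range(n_sub):
            pos = rng.integers(cfg.seq_len)
            seq[pos] = (seq[pos] + rng.integers(1, 4)) % 4
        if node.is_leaf():
            seqs[node.taxon.label] = seq
        else:
            for child in node.child_nodes():
                evolve(child, seq)

    root = tree.tree.seed_node
    evolve(root, root_seq)

    records = [
        HaplotypeRecord(lab, lab, "".join(_NUC[seqs[lab]]))
        for lab in sorted(seqs)
    ]
    return HaplotypeAlignment(records)


def simulate_individuals(
    haplos: HaplotypeAlignment,
    species_of_haplotype: dict[str, int],
    cfg: SimConfig,
) -> tuple[HaplotypeAlignment, TruthTable]:
    """Assign haplotypes to diploid individuals.

    A non-hybrid individual draws one haplotype (or two distinct ones with
    probability ``het_rate``) from its species pool; a hybrid draws one
    haplotype from each of two distinct species. Haplotypes are renamed
    ``<individual><a|b>`` for heterozygotes.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    pools: dict[int, list[str]] = {}
    for hap, sp in species_of_haplotype.items():
        pools.setdefault(sp, []).append(hap)
    for sp, pool in pools.items():
        pool.sort()
        if cfg.het_rate > 0 and len(pool) < 2:
            raise ValueError(f"species {sp} needs >= 2 haplotypes for heterozygotes")

    seq_of = {r.haplotype_id: r.sequence for r in haplos.records}
    truth = TruthTable()
    records: list[HaplotypeRecord] = []
    ind_counter = 0
    for sp in sorted(pools):
        for _ in range(cfg.n_individuals_per_species):
            ind_counter += 1
            ind = f"i{ind_counter:03d}"
            if cfg.K_species > 1 and rng.random() < cfg.hybrid_fraction:
                other = int(rng.choice([s for s in sorted(pools) if s != sp]))
                pair = sorted((sp, other))
                truth.hybrid_parents[ind] = (pair[0], pair[1])
                chosen = [
                    str(rng.choice(pools[pair[0]])),
                    str(rng.choice(pools[pair[1]])),
                ]
            elif rng.random() < cfg.het_rate:
                chosen = [str(h) for h in rng.choice(pools[sp], size=2, replace=False)]
            else:
                chosen = [str(rng.choice(pools[sp]))]
            truth.species_of[ind] = sp
            truth.haplotypes_of[ind] = []
            for k, hap in enumerate(chosen):
                hid = ind + ("abcd"[k] if len(chosen) > 1 else "")
                records.append(HaplotypeRecord(hid, ind, seq_of[hap]))
                truth.haplotypes_of[ind].append(hid)
                truth.species_of_haplotype[hid] = species_of_haplotype[hap]
    return HaplotypeAlignment(records), truth


def simulate_bands(truth: TruthTable, cfg: SimConfig) -> BandMatrix:
    """Cluster-structured dominant-marker bands.

    Each marker gets a home species (round-robin); its band is present with
    probability ``band_major`` inside the home species and ``band_minor``
    outside. A hybrid uses the larger of its two parental probabilities —
    dominant markers show a band if either parental genome carries it.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    individuals = sorted(truth.species_of)
    markers = [f"m{j + 1:02d}" for j in range(cfg.n_markers)]
    home = [j % cfg.K_species for j in range(cfg.n_markers)]
    values = np.zeros((len(individuals), cfg.n_markers))
    for i, ind in enumerate(individuals):
        sources = (
            truth.hybrid_parents[ind]
            if ind in truth.hybrid_parents
            else (truth.species_of[ind],)
        )
        for j in range(cfg.n_markers):
            p = max(
                cfg.band_major if home[j] == s else cfg.band_minor for s in sources
            )
            values[i, j] = float(rng.random() < p)
    return BandMatrix(individuals=individuals, markers=markers, values=values)


def _ordinal_score(latent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Average of two independent 5-level scorings of a latent value."""
    cuts = np.array([-1.5, -0.5, 0.5, 1.5])
    s1 = np.digitize(latent + rng.normal(0, 0.3, latent.shape), cuts) + 1
    s2 = np.digitize(latent + rng.normal(0, 0.3, latent.shape), cuts) + 1
    return (s1 + s2) / 2.0


def simulate_morphology(truth: TruthTable, cfg: SimConfig) -> MorphoTable:
    """Unit-structured mixed-type morphology.

    Unit mean vectors are drawn i.i.d. normal with SD ``effect_size /
    sqrt(2)`` per coordinate over an informative core of ``n_informative``
    variables (evenly spread across the blocks; all other variables are pure
    noise), so the expected pairwise between-unit shift on an informative
    variable is ``effect_size`` within-unit SDs. Continuous variables add unit-variance
    noise; ordinal variables cut a latent normal into 5 levels averaged over
    two scorings (half-steps); binary variables threshold the latent at 0.
    Hybrids sit at the parental mean midpoint. The first ``n_duplicate``
    continuous variables are duplicated with |r| > 0.9 twins appended, to
    exercise collinearity pruning.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    p = cfg.n_cont + cfg.n_ord + cfg.n_bin
    # only an informative core of variables discriminates units, evenly
    # spread across the continuous/ordinal/binary blocks
    n_inf = p if cfg.n_informative is None else min(cfg.n_informative, p)
    informative = np.unique(np.linspace(0, p - 1, n_inf).round().astype(int))
    mask = np.zeros(p)
    mask[informative] = 1.0
    unit_means = {
        sp: rng.normal(0.0, cfg.effect_size / np.sqrt(2.0), size=p) * mask
        for sp in range(cfg.K_species)
    }
    truth.unit_means = {str(sp): mu for sp, mu in unit_means.items()}

    individuals = sorted(truth.species_of)
    rows = []
    for ind in individuals:
        if ind in truth.hybrid_parents:
            a, b = truth.hybrid_parents[ind]
            mu = (unit_means[a] + unit_means[b]) / 2.0
        else:
            mu = unit_means[truth.species_of[ind]]
        latent = mu + rng.normal(0.0, 1.0, size=p)
        row = np.empty(p)
        row[: cfg.n_cont] = latent[: cfg.n_cont]
        row[cfg.n_cont : cfg.n_cont + cfg.n_ord] = _ordinal_score(
            latent[cfg.n_cont : cfg.n_cont + cfg.n_ord], rng
        )
        row[cfg.n_cont + cfg.n_ord :] = (latent[cfg.n_cont + cfg.n_ord :] > 0).astype(
            float
        )
        rows.append(row)
    X = np.vstack(rows)

    variables = (
        [f"cont{k + 1:02d}" for k in range(cfg.n_cont)]
        + [f"ord{k + 1:02d}" for k in range(cfg.n_ord)]
        + [f"bin{k + 1:02d}" for k in range(cfg.n_bin)]
    )
    kinds = {v: "continuous" for v in variables[: cfg.n_cont]}
    kinds.update(
        {v: "ordinal" for v in variables[cfg.n_cont : cfg.n_cont + cfg.n_ord]}
    )
    kinds.update({v: "binary" for v in variables[cfg.n_cont + cfg.n_ord :]})

    n_dup = min(cfg.n_duplicate, cfg.n_cont)
    if n_dup:
        twins = X[:, :n_dup] + rng.normal(0.0, 0.2, size=(X.shape[0], n_dup))
        X = np.hstack([X, twins])
        for k in range(n_dup):
            name = f"cont{k + 1:02d}_dup"
            variables.append(name)
            kinds[name] = "continuous"

    return MorphoTable(
        accessions=individuals, variables=variables, kinds=kinds, values=X
    )


def simulate_dataset(cfg: SimConfig):
    """Run the full generator chain; returns
    (tree, haplotype alignment, individuals alignment, bands, morphology, truth)."""
    tree, sp_of_hap = simulate_species_tree(cfg)
    pool = simulate_haplotypes(tree, cfg, sp_of_hap)
    aln, truth = simulate_individuals(pool, sp_of_hap, cfg)
    bands = simulate_bands(truth, cfg)
    morpho = simulate_morphology(truth, cfg)
    return tree, pool, aln, bands, morpho, truth
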