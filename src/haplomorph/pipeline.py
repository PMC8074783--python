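"""End-to-end orchestration: data -> distances -> delimitation -> marker
integration -> morphospace -> machine-readable report.

The pipeline runs either on external files (FASTA + newick + CSVs) or on a
simulated scenario with known truth. Every number in the report is
recomputable from the inputs and the configuration; the report body is
byte-identical on rerun with the same seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .delimit import abgd_over_grid, build_haploweb, clusters_from_tree, gmyc_single_threshold
from .distances import (
    GdBandConfig,
    count_species_conservative,
    gdmin_crosstable,
    jaccard_distance_matrix,
    pairwise_distance_matrix,
)
from .integrate import double_factorize, refine_subclusters
from .io import read_fasta, read_newick, read_tables
from .morphospace import (
    classify_aberrance,
    fit_da,
    goodman_kruskal_lambda,
    kruskal_wallis_axes,
    morphoclouds,
    prune_collinear,
    select_variables_lasso,
    ward_morphotypes,
)
from .simulate import SimConfig, simulate_dataset

log = logging.getLogger("haplomorph")

__all__ = ["PipelineConfig", "run_pipeline", "validate_report"]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; defaults mirror the printed analysis
    settings (support threshold 0.6, 7 Ward groups, |r| <= 0.80, 3 cloud
    axes)."""

    fasta: str | None = None
    tree: str | None = None
    bands: str | None = None
    morphology: str | None = None
    morphology_meta: str | None = None
    units_table: str | None = None
    sim: SimConfig | None = None
    band_config: GdBandConfig = field(default_factory=GdBandConfig)
    min_support: float = 0.6
    abgd_prior_grid: tuple[float, ...] = (0.001, 0.00215, 0.00464, 0.01, 0.0215, 0.0464)
    abgd_rel_gap: float = 1.5
    k_ward: int = 7
    r_max: float = 0.80
    cloud_axes: int = 3
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        has_files = self.fasta is not None
        if has_files == (self.sim is not None):
            raise ValueError("provide either input paths or a SimConfig, not both")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_json_safe(v) for v in sorted(obj, key=str) if True] if isinstance(
            obj, set
        ) else [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def validate_report(report: dict) -> None:
    """Structural validation of a report against the shipped schema.

    A lightweight checker (required keys, basic types and bounds) for the
    subset of JSON Schema used in ``report_schema.json``; raises
    ``ValueError`` on the first violation.
    """
    schema = json.loads(
        (Path(__file__).parent / "report_schema.json").read_text()
    )

    def check(obj, spec, path="report"):
        typ = spec.get("type")
        if typ == "object":
            if not isinstance(obj, dict):
                raise ValueError(f"{path}: expected object")
            for key in spec.get("required", []):
                if key not in obj:
                    raise ValueError(f"{path}: missing required key {key!r}")
            for key, sub in spec.get("properties", {}).items():
                if key in obj:
                    check(obj[key], sub, f"{path}.{key}")
        elif typ == "array":
            if not isinstance(obj, list):
                raise ValueError(f"{path}: expected array")
            if "minItems" in spec and len(obj) < spec["minItems"]:
                raise ValueError(f"{path}: too few items")
            if "maxItems" in spec and len(obj) > spec["maxItems"]:
                raise ValueError(f"{path}: too many items")
            for i, item in enumerate(obj):
                if "items" in spec:
                    check(item, spec["items"], f"{path}[{i}]")
        elif typ == "integer":
            if not isinstance(obj, (int, np.integer)) or isinstance(obj, bool):
                raise ValueError(f"{path}: expected integer, got {obj!r}")
            if "minimum" in spec and obj < spec["minimum"]:
                raise ValueError(f"{path}: {obj} below minimum {spec['minimum']}")
        elif typ == "number":
            if not isinstance(obj, (int, float, np.floating, np.integer)):
                raise ValueError(f"{path}: expected number, got {obj!r}")
            if "minimum" in spec and obj < spec["minimum"]:
                raise ValueError(f"{path}: {obj} below minimum")
            if "maximum" in spec and obj > spec["maximum"]:
                raise ValueError(f"{path}: {obj} above maximum")
        elif typ == "string":
            if not isinstance(obj, str):
                raise ValueError(f"{path}: expected string, got {obj!r}")

    check(report, schema)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order and return the report dictionary.

    A missing morphology block skips the morphospace stage (marked
    ``skipped``); any stage failure aborts with the stage name attached.
    """
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
        },
        "warnings": [],
    }
    stage = "load"
    try:
        truth = None
        bands = morpho = units = None
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if cfg.sim is not None:
                tree, _pool, aln, bands, morpho, truth = simulate_dataset(cfg.sim)
                units = truth.unit_assignment()
            else:
                aln = read_fasta(cfg.fasta)
                tree = read_newick(cfg.tree) if cfg.tree else None
                if cfg.bands and cfg.morphology and cfg.units_table:
                    bands, morpho, units = read_tables(
                        cfg.bands, cfg.morphology, cfg.morphology_meta, cfg.units_table
                    )
            report["data"] = {
                "n_sequences": len(aln),
                "alignment_length": aln.length,
                "n_individuals": len(aln.individuals()),
            }

            stage = "distances"
            dm = pairwise_distance_matrix(aln, model="k2p")
            gd = None
            if units is not None:
                gd = gdmin_crosstable(dm, units, cfg.band_config)
                report["distances"] = {
                    "units": gd.units,
                    "gdmin_pct": _json_safe(gd.M.tolist()),
                    "band": [[str(b) for b in row] for row in gd.band],
                    "conservative_species_count": count_species_conservative(gd),
                }

            stage = "delimitation"
            web = build_haploweb(aln)
            delim: dict = {"ffr_count": web.n_ffr}
            finite = np.nan_to_num(dm.D, nan=0.0)
            abgd = abgd_over_grid(
                dm.labels, finite, list(cfg.abgd_prior_grid), cfg.abgd_rel_gap
            )
            delim["abgd_group_counts"] = dict(
                zip(map(str, abgd.prior_grid), abgd.group_counts)
            )
            delim["abgd_range"] = [min(abgd.group_counts), max(abgd.group_counts)]
            if tree is not None:
                clades = clusters_from_tree(tree, cfg.min_support)
                delim["tree_cluster_count"] = len(clades)
                if tree.ultrametric_deviation <= 1e-6 and len(tree.leaf_names) >= 4:
                    fit = gmyc_single_threshold(tree)
                    delim["gmyc"] = {
                        "n_entities": fit.n_entities,
                        "LR": _json_safe(fit.LR),
                        "p_value": _json_safe(fit.p_value),
                        "threshold_time": _json_safe(fit.threshold_time),
                        "window_size": len(fit.support_interval),
                    }
            report["delimitation"] = delim

            stage = "integration"
            if bands is not None:
                jac = jaccard_distance_matrix(bands)
                ind_labels = sorted(aln.individuals())
                # collapse haplotype distances to individual minima for fusion
                idx_of = {lab: i for i, lab in enumerate(dm.labels)}
                n_ind = len(ind_labels)
                Di = np.zeros((n_ind, n_ind))
                groups = {
                    ind: [idx_of[r.haplotype_id] for r in recs]
                    for ind, recs in aln.individuals().items()
                }
                for a in range(n_ind):
                    for b in range(a + 1, n_ind):
                        block = finite[
                            np.ix_(groups[ind_labels[a]], groups[ind_labels[b]])
                        ]
                        Di[a, b] = Di[b, a] = block.min()
                from .distances import DistanceMatrix

                its_ind = DistanceMatrix(labels=ind_labels, D=Di, metric_name="k2p-min")
                combo = double_factorize(its_ind, jac)
                base = None
                if units is not None:
                    base = {
                        lab: units.main_cluster(lab) or "?"
                        for lab in combo.model.labels
                    }
                sub = refine_subclusters(combo, base)
                report["integration"] = {
                    "variance_share_1_2": _json_safe(
                        combo.model.variance_share[:2].tolist()
                    ),
                    "n_subclusters": len(set(sub.values())),
                    "subclusters": sub,
                }

            stage = "morphospace"
            if morpho is not None and units is not None:
                pruned = prune_collinear(morpho, cfg.r_max)
                ward = ward_morphotypes(pruned, min(cfg.k_ward, len(pruned.accessions)))
                gk = goodman_kruskal_lambda(
                    ward, {a: units.unit_of[a] for a in ward if a in units.unit_of}
                )
                subsets = select_variables_lasso(pruned, units, seed=cfg.seed)
                best = min(
                    (s for s in subsets if s.n_variables >= 2),
                    key=lambda s: s.n_variables,
                    default=None,
                )
                # the constrained DA runs on the selected subset only; a DA
                # on the full pruned block would be singular at desk-scale n
                da = fit_da(
                    pruned.subset(best.variables) if best is not None else pruned,
                    units,
                )
                kw = kruskal_wallis_axes(
                    da.scores[:, : min(2, da.scores.shape[1])], da.labels, ward
                )
                morpho_rep: dict = {
                    "n_variables_after_pruning": len(pruned.variables),
                    "n_pruned": len(morpho.variables) - len(pruned.variables),
                    "ward_groups": len(set(ward.values())),
                    "goodman_kruskal_lambda": _json_safe(gk),
                    "kruskal_wallis_p": _json_safe(kw),
                    "wilks_lambda": _json_safe(da.wilks_lambda),
                    "wilks_p": _json_safe(da.wilks_p),
                    "axis1_dispersion_pct": _json_safe(float(da.dispersion_share[0])),
                    "subsets": [
                        {
                            "selector": s.selector,
                            "penalty": _json_safe(s.penalty),
                            "n_variables": s.n_variables,
                            "axis1_dispersion": _json_safe(s.axis1_dispersion),
                            "cum_dispersion_1_3": _json_safe(s.cum_dispersion_1_3),
                            "stewart_love_1_6": _json_safe(s.stewart_love_1_6),
                            "glm_r2": _json_safe(s.glm_r2),
                        }
                        for s in subsets
                    ],
                }
                if best is not None and best.n_variables >= 2:
                    clouds = morphoclouds(da, n_axes=cfg.cloud_axes)
                    ab = classify_aberrance(clouds, units, da, n_axes=cfg.cloud_axes)
                    morpho_rep["n_min"] = best.n_variables
                    morpho_rep["morphoclouds"] = len(set(clouds.cloud_of.values()))
                    morpho_rep["aberrance_pct"] = _json_safe(ab.proportions)
                report["morphospace"] = morpho_rep
            else:
                report["morphospace"] = {"skipped": True}

            if truth is not None:
                report["truth"] = {
                    "K_species": cfg.sim.K_species,
                    "n_hybrids": len(truth.hybrid_parents),
                }
            report["warnings"] = sorted({str(w.message) for w in caught})
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        log.error("stage %s failed: %s", stage, exc)
        raise

    validate_report(_json_safe(report))
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(_json_safe(report), indent=2, sort_keys=True)
        )
    return report
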