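"""End-to-end orchestration: load a study dataset, run every stage, report.

Stage order follows the study design: clone detection on raw genotypes ->
genets-only subset -> dosage restoration -> Bruvo distances and PCoA ->
admixture taxon calls -> leaf FCM ploidy bins -> seed screen pathway
inference and reproduction table -> morphometrics chain (GPA, outlier
filter, averaging, TPS imputation, relative warps, fruit PCA, trait pruning,
CDA with passive hybrids, LOO-LDA).  Everything is deterministic given the
configuration seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import admixture as adx
from . import cytometry as cyt
from . import genotypes as gen
from . import io as cio
from . import morphometrics as mm
from .util import largest_remainder_percentages

logger = logging.getLogger("crataegus")

__all__ = [
    "PipelineConfig",
    "StudyDataset",
    "Report",
    "load_dataset",
    "run_full_analysis",
    "write_report",
]


@dataclass
class PipelineConfig:
    """All tunable thresholds, surfaced with their study defaults."""

    seed: int = 0
    clone_threshold: float = 22.0       # stepwise mutation steps
    clone_metric: str = "stepwise"
    admixture_lower: float = 0.15
    admixture_upper: float = 0.85
    fcss_tol: float = 0.25              # ploidy matching tolerance (x units)
    fcss_smax: int = 4                  # max endosperm sperm contribution
    r_max: float = 0.9                  # Spearman pruning threshold
    mad_multiplier: float = 2.0
    min_shared_loci: int = 10
    gmm_max_components: int = 6
    leaf_base_ploidy: int = 2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class StudyDataset:
    """Validated in-memory view of all input files."""

    genotypes: list[gen.Genotype]
    loci: dict[str, gen.Locus]
    qmatrix: pd.DataFrame | None = None
    cluster_map: adx.ClusterSpeciesMap | None = None
    fcm: pd.DataFrame | None = None
    seeds: pd.DataFrame | None = None
    leaves_fl: list[dict] = field(default_factory=list)
    leaves_sh: list[dict] = field(default_factory=list)
    fruits: pd.DataFrame | None = None
    group_labels: dict[str, str] = field(default_factory=dict)


@dataclass
class Report:
    """All output tables plus run metadata."""

    tables: dict[str, pd.DataFrame]
    metadata: dict


def load_dataset(paths: Mapping[str, str], config: PipelineConfig) -> StudyDataset:
    """Load and cross-validate the study files.

    ``paths`` keys: genotypes, loci, qmatrix, cluster_map, fcm, seeds,
    leaves_fl, leaves_sh, fruits (all optional except genotypes + loci).
    Landmark records must have exactly 13 points; alleles outside a locus
    size window are dropped with a warning at read time.
    """
    loci = cio.read_locus_csv(paths["loci"])
    genotypes = cio.read_genotype_csv(paths["genotypes"], loci)
    ds = StudyDataset(genotypes=genotypes, loci=loci)
    ids = {g.individual_id for g in genotypes}
    ds.group_labels = {
        g.individual_id: (g.taxon_label or g.population_id) for g in genotypes
    }
    if "qmatrix" in paths:
        ds.qmatrix = cio.read_qmatrix_csv(paths["qmatrix"])
        stray = set(ds.qmatrix.index) - ids
        if stray:
            raise ValueError(f"Q-matrix ids not in genotypes: {sorted(stray)[:5]}")
    if "cluster_map" in paths:
        ds.cluster_map = cio.read_cluster_map_csv(paths["cluster_map"])
    elif ds.qmatrix is not None:
        ds.cluster_map = adx.ClusterSpeciesMap.default_crataegus()
    if "fcm" in paths:
        ds.fcm = pd.read_csv(paths["fcm"])
    if "seeds" in paths:
        ds.seeds = pd.read_csv(paths["seeds"])
    for key in ("leaves_fl", "leaves_sh"):
        if key in paths:
            setattr(ds, key, cio.read_tps(paths[key], expect_landmarks=13))
    if "fruits" in paths:
        ds.fruits = pd.read_csv(paths["fruits"], index_col="individual_id")
    return ds


def _leaf_ploidies(fcm: pd.DataFrame, config: PipelineConfig):
    leaf = fcm[fcm["tissue"] == "leaf"]
    binning = cyt.fit_ploidy_bins(
        leaf["index"], base_ploidy=config.leaf_base_ploidy,
        max_components=config.gmm_max_components, context=("leaf", "Pisum"),
        random_state=config.seed,
    )
    labels = leaf["index"].map(lambda x: cyt.assign_ploidy(x, binning, "nearest"))
    out = pd.DataFrame(
        {"sample_id": leaf["sample_id"], "taxon": leaf["taxon"],
         "index": leaf["index"], "ploidy_label": labels}
    ).set_index("sample_id")
    return binning, out


def _seed_ploidies(seeds: pd.DataFrame, diploid_equiv_index: float):
    """Convert seed tissue indices to ploidies on a half-integer grid.

    ``diploid_equiv_index`` is the index a diploid tissue shows against the
    seed standard; a tissue of ploidy p indexes ``p/2`` times that.
    """
    out = seeds.copy()
    for col, new in (("embryo_index", "embryo"), ("endosperm_index", "endosperm")):
        frac = 2.0 * out[col] / diploid_equiv_index
        out[new] = (frac * 2).round() / 2.0
    return out


def run_full_analysis(dataset: StudyDataset, config: PipelineConfig) -> Report:
    """Run every stage the dataset supports and collect the report tables."""
    tables: dict[str, pd.DataFrame] = {}

    # --- clones on raw (unrestored) genotypes ---------------------------
    logger.info("stage=clones computing %s distances", config.clone_metric)
    dist = gen.pairwise_distance_matrix(
        dataset.genotypes, dataset.loci, metric=config.clone_metric,
        min_shared_loci=config.min_shared_loci,
    )
    assignment = gen.detect_clones(dist, config.clone_threshold)
    tables["clonality"] = gen.summarize_clonality(assignment, dataset.group_labels)
    genet_of = dict(zip(assignment.ids, assignment.genet_ids))

    # --- genets-only subset, dosage restoration, Bruvo PCoA -------------
    genet_reps = sorted(set(assignment.genet_ids))
    genets = [g for g in dataset.genotypes if g.individual_id in set(genet_reps)]
    logger.info("stage=genotypes %d genets of %d ramets", len(genets),
                len(dataset.genotypes))
    restored = gen.restore_dosage(genets)
    bruvo = gen.pairwise_distance_matrix(
        restored, dataset.loci, metric="bruvo",
        min_shared_loci=config.min_shared_loci,
    )
    ordination = gen.pcoa(bruvo, n_axes=2)
    scores = ordination.coordinates.copy()
    scores["group"] = [dataset.group_labels[i] for i in scores.index]
    tables["pcoa_scores"] = scores
    tables["pcoa_variance"] = pd.DataFrame(
        {"axis": [f"PCo{i+1}" for i in range(len(ordination.pct_variance))],
         "pct_variance": ordination.pct_variance}
    )

    # --- admixture taxon calls ------------------------------------------
    if dataset.qmatrix is not None and dataset.cluster_map is not None:
        q_genets = dataset.qmatrix.loc[
            [i for i in dataset.qmatrix.index if i in set(genet_reps)]
        ]
        calls = adx.classify_qmatrix(
            q_genets, dataset.cluster_map,
            lower=config.admixture_lower, upper=config.admixture_upper,
        )
        tables["taxon_calls"] = calls

    # --- flow cytometry + seed screen -----------------------------------
    if dataset.fcm is not None:
        binning, leaf_ploidy = _leaf_ploidies(dataset.fcm, config)
        tables["leaf_ploidy"] = leaf_ploidy
        counts = leaf_ploidy["ploidy_label"].value_counts().to_dict()
        pct = largest_remainder_percentages(counts)
        tables["ploidy_frequency"] = pd.DataFrame(
            [{"ploidy": k, "n": counts[k], "pct": pct[k]}
             for k in sorted(counts)]
        )
        tables["ploidy_bins"] = pd.DataFrame(
            [{"label": c.label, "mean": c.mean, "sd": c.sd,
              "low": c.low, "high": c.high} for c in binning.components]
        )
        if dataset.seeds is not None:
            # diploid-mother embryos are overwhelmingly diploid, so their
            # median index calibrates the diploid-equivalent scale of the
            # seed standard; without diploid mothers fall back to the lowest
            # embryo mode.
            if (dataset.seeds["maternal_ploidy"] == 2).any():
                seed_base = float(
                    np.median(dataset.seeds["embryo_index"]
                              [dataset.seeds["maternal_ploidy"] == 2])
                )
            else:
                seed_base = float(dataset.seeds["embryo_index"].min())
            seeds = _seed_ploidies(dataset.seeds, seed_base)
            detail, aggregate = cyt.summarize_reproduction(
                seeds, tol=config.fcss_tol, smax=config.fcss_smax,
            )
            tables["reproduction_detail"] = detail
            tables["reproduction_summary"] = aggregate.reset_index()

    # --- morphometrics ---------------------------------------------------
    if dataset.leaves_fl and dataset.leaves_sh and dataset.fruits is not None:
        tables.update(_morphometrics_stage(dataset, genet_of, config))

    meta = {
        "config": PipelineConfig().to_dict() | config.to_dict(),
        "n_individuals": len(dataset.genotypes),
        "n_genets": len(genet_reps),
    }
    return Report(tables=tables, metadata=meta)


def _individual_of(record_id: str) -> str:
    """Leaf specimen ids are '<individual>_fl0' / '<individual>_sh1'."""
    return record_id.rsplit("_", 1)[0]


def _morphometrics_stage(dataset: StudyDataset, genet_of, config: PipelineConfig):
    tables = {}
    blocks = {}
    for shoot, records in (("fl", dataset.leaves_fl), ("sh", dataset.leaves_sh)):
        coords = np.stack([r["coords"] for r in records])
        ids = [_individual_of(r["id"]) for r in records]
        aligned = mm.gpa_align(coords)
        keep, _ = mm.filter_outlier_shapes(aligned.aligned, ids)
        by_ind: dict[str, list[np.ndarray]] = {}
        for shp, ind, k in zip(aligned.aligned, ids, keep):
            if k:
                by_ind.setdefault(ind, []).append(shp)
        blocks[shoot] = {i: np.stack(v) for i, v in by_ind.items()}
    ids, composites = mm.average_and_combine(blocks["fl"], blocks["sh"])
    composites, kept, _ = mm.impute_missing_landmarks(composites)
    ids = [i for i, k in zip(ids, kept) if k]
    composites = composites[kept]
    rw = mm.relative_warps(composites)
    rw_scores = pd.DataFrame(rw.scores[:, :2], index=ids, columns=["RW1", "RW2"])
    tables["relative_warps"] = rw_scores
    tables["relative_warp_variance"] = pd.DataFrame(
        {"axis": [f"RW{i+1}" for i in range(len(rw.pct_variance))],
         "pct_variance": rw.pct_variance}
    )

    fruits = dataset.fruits.loc[[i for i in ids if i in dataset.fruits.index]]
    fruit_traits = fruits.drop(columns=[c for c in ("taxon",) if c in fruits])
    tables["fruit_pca_variance"] = pd.DataFrame(
        {"axis": [f"PC{i+1}" for i in range(len(mm.pca_traits(fruit_traits).pct_variance))],
         "pct_variance": mm.pca_traits(fruit_traits).pct_variance}
    )

    # combined trait table: Procrustes coordinates as individual traits
    coord_cols = {}
    for j in range(composites.shape[1]):
        coord_cols[f"lm{j+1}_x"] = composites[:, j, 0]
        coord_cols[f"lm{j+1}_y"] = composites[:, j, 1]
    traits = pd.DataFrame(coord_cols, index=ids)
    traits = traits.join(fruit_traits, how="inner")
    groups = pd.Series({i: dataset.group_labels[i] for i in traits.index})
    parents = traits.index[groups.isin(["L", "M", "R"])]
    hybrids = traits.index[~groups.isin(["L", "M", "R"])]
    pruned, _ = mm.prune_correlated(traits.loc[parents], r_max=config.r_max)
    model = mm.cda_with_passive(
        pruned, groups.loc[parents],
        passive=traits.loc[hybrids, pruned.columns] if len(hybrids) else None,
        ridge=1e-8,
    )
    tables["cda_scores"] = model.active_scores.assign(group=groups.loc[parents])
    if model.passive_scores is not None:
        tables["cda_passive_scores"] = model.passive_scores.assign(
            group=groups.loc[hybrids]
        )
    loo = mm.loo_lda(model.active_scores, groups.loc[parents])
    tables["loo_confusion_parents"] = loo.confusion
    tables["loo_accuracy"] = pd.DataFrame(
        [{"dataset": "parents", "accuracy_pct": loo.accuracy_pct}]
    )
    return tables


def write_report(report: Report, out_dir) -> list[str]:
    """Write one CSV per table plus a JSON manifest with checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in report.tables.items():
        path = out / f"{name}.csv"
        table.to_csv(path, float_format="%.6g")
        written.append(path.name)
    manifest = {
        "metadata": report.metadata,
        "files": {},
    }
    for name in written:
        digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
        manifest["files"][name] = digest
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return written + ["manifest.json"]
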