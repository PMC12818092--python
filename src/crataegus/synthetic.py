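"""Synthetic hawthorn datasets with known ground truth.

Every pipeline stage is testable without field data: the generator emits
genotype tables, admixture Q-matrices, flow-cytometry indices, seed screens
and leaf/fruit morphology whose true taxa, genets, ploidies, reproductive
pathways and shape templates are all recorded.

The default configuration is a structural replica of the study design it
emulates: 22 nuSSR loci; taxa L, M, R plus hybrids MED (L×M), MAC (L×R),
SUB (M×R) at the published sample sizes; L/M/MED essentially diploid, R and
MAC tri-/tetraploid, SUB mixed; a diploid leaf index of 0.19 against the
*Pisum* standard; clone structure concentrated in R and its hybrids; R
reproducing ~10% sexually and mostly by pseudogamous apomixis, the diploids
almost purely sexually.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genotypes import Genotype, Locus

__all__ = [
    "TaxonSpec",
    "CloneSpec",
    "FcmSpec",
    "MorphologySpec",
    "SimulationConfig",
    "default_config",
    "simulate_genotypes",
    "simulate_fcm_and_seeds",
    "simulate_morphology",
    "simulate_all",
]

SPECIES = ("L", "M", "R")
HYBRID_PARENTS = {"MED": ("L", "M"), "MAC": ("L", "R"), "SUB": ("M", "R")}
SUBGROUPS = {"L": ("L1", "L2"), "M": ("MON",), "R": ("R1", "R2", "R3")}


@dataclass
class CloneSpec:
    """How many genets of a taxon are clonal and how large the clones are."""

    n_clones: int = 0
    ramets_per_clone: int = 3
    max_mutation_steps: int = 5


@dataclass
class TaxonSpec:
    n: int
    ploidy: dict[int, float]                  # ploidy -> probability
    reproduction: dict[str, float]            # pathway -> probability
    clones: CloneSpec = field(default_factory=CloneSpec)

    def __post_init__(self) -> None:
        for name, probs in (("ploidy", self.ploidy),
                            ("reproduction", self.reproduction)):
            if probs and abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        if self.n <= 0:
            raise ValueError("taxon sample size must be positive")


@dataclass
class FcmSpec:
    """Fluorescence-index scales: a diploid leaf indexes ~0.19 against
    *Pisum*; seed tissues are measured against *Carex* on a larger scale."""

    leaf_base_index: float = 0.19     # diploid leaf / Pisum
    leaf_sd: float = 0.008
    seed_base_index: float = 2.3      # diploid-equivalent / Carex
    seed_rel_sd: float = 0.015
    seeds_per_mother: int = 5

    def __post_init__(self) -> None:
        if self.leaf_sd <= 0 or self.seed_rel_sd <= 0:
            raise ValueError("coefficients of variation must be positive")


@dataclass
class MorphologySpec:
    leaves_per_shoot: tuple[int, int] = (2, 3)   # min, max per shoot type
    individual_sd: float = 0.02    # between-tree shape noise per coordinate
    leaf_sd: float = 0.02          # within-tree (leaf-level) noise
    fruit_rel_sd: float = 0.06     # fruit trait cv
    # hybrid classes are morphologically far more variable than the parental
    # species (backcrosses and advanced hybrids overlap both parents)
    hybrid_sd_scale: float = 3.0


@dataclass
class SimulationConfig:
    seed: int
    taxa: dict[str, TaxonSpec]
    n_loci: int = 22
    allele_ladder: int = 8         # distinct alleles per species per locus
    ladder_step: int = 3           # repeat units between neighbouring alleles
    divergence_steps: float = 12.0  # repeat-unit offset between species ladders
    dirichlet_alpha: float = 1.0
    q_concentration: float = 200.0
    fcm: FcmSpec = field(default_factory=FcmSpec)
    morphology: MorphologySpec = field(default_factory=MorphologySpec)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an RNG seed is mandatory")


def default_config(seed: int) -> SimulationConfig:
    """The default study conditions (published sample sizes and structure)."""
    return SimulationConfig(
        seed=seed,
        taxa={
            "L": TaxonSpec(
                n=111, ploidy={2: 0.95, 3: 0.05},
                reproduction={"sexual": 0.96, "pseudogamous": 0.025,
                              "autonomous": 0.015},
                clones=CloneSpec(n_clones=1, ramets_per_clone=3),
            ),
            "M": TaxonSpec(
                n=32, ploidy={2: 0.94, 3: 0.06},
                reproduction={"sexual": 1.0},
            ),
            "R": TaxonSpec(
                n=71, ploidy={3: 0.81, 4: 0.19},
                reproduction={"sexual": 0.10, "pseudogamous": 0.88,
                              "autonomous": 0.02},
                clones=CloneSpec(n_clones=11, ramets_per_clone=5),
            ),
            "MED": TaxonSpec(
                n=17, ploidy={2: 1.0},
                reproduction={"sexual": 1.0},
            ),
            "MAC": TaxonSpec(
                n=57, ploidy={3: 0.84, 4: 0.16},
                reproduction={"sexual": 0.30, "pseudogamous": 0.68,
                              "autonomous": 0.02},
                clones=CloneSpec(n_clones=11, ramets_per_clone=4),
            ),
            "SUB": TaxonSpec(
                n=18, ploidy={2: 0.22, 3: 0.67, 4: 0.11},
                reproduction={"sexual": 0.34, "pseudogamous": 0.64,
                              "autonomous": 0.02},
                clones=CloneSpec(n_clones=5, ramets_per_clone=2),
            ),
        },
    )


def small_config(seed: int) -> SimulationConfig:
    """A scaled-down study (same structure, ~60 individuals) for quick
    exploratory runs; taxon-level proportions match :func:`default_config`."""
    cfg = default_config(seed)
    scale = {"L": 18, "M": 10, "R": 16, "MED": 5, "MAC": 12, "SUB": 6}
    clones = {"L": CloneSpec(), "M": CloneSpec(),
              "R": CloneSpec(n_clones=3, ramets_per_clone=3),
              "MED": CloneSpec(),
              "MAC": CloneSpec(n_clones=2, ramets_per_clone=3),
              "SUB": CloneSpec(n_clones=1, ramets_per_clone=2)}
    for taxon, spec in cfg.taxa.items():
        spec.n = scale[taxon]
        spec.clones = clones[taxon]
    return cfg


# ---------------------------------------------------------------------------
# genotypes + Q-matrix


def _make_loci(config: SimulationConfig) -> dict[str, Locus]:
    motifs = [2, 3, 4]
    loci = {}
    for i in range(config.n_loci):
        motif = motifs[i % len(motifs)]
        name = f"ssr{i + 1:02d}"
        loci[name] = Locus(name, motif, (100, 500))
    return loci


def _species_frequencies(
    config: SimulationConfig, loci: Mapping[str, Locus], rng: np.random.Generator
) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Per species and locus: (allele sizes in bp, sampling probabilities).

    Each species draws Dirichlet frequencies over its own allele ladder; the
    ladders of different species are offset by ``divergence_steps`` repeat
    units, which controls between-species distances.
    """
    freqs: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for s_idx, species in enumerate(SPECIES):
        freqs[species] = {}
        for l_idx, (name, locus) in enumerate(loci.items()):
            span = (config.allele_ladder * config.ladder_step
                    + len(SPECIES) * config.divergence_steps) * locus.motif_length
            center = 150 + 17 * (l_idx % 7)  # deterministic per-locus anchor
            center = min(max(center, locus.size_window[0] + 10),
                         locus.size_window[1] - int(span) - 10)
            offset = int(round(s_idx * config.divergence_steps))
            sizes = np.array(
                [center + locus.motif_length * (offset + j * config.ladder_step)
                 for j in range(config.allele_ladder)]
            )
            p = rng.dirichlet(np.full(config.allele_ladder, config.dirichlet_alpha))
            freqs[species][name] = (sizes, p)
    return freqs


def _draw_alleles(freq, k, rng):
    sizes, p = freq
    return tuple(sorted(int(a) for a in rng.choice(sizes, size=k, p=p)))


def _mutate(genotype: Genotype, loci: Mapping[str, Locus], steps: int,
            rng: np.random.Generator) -> Genotype:
    alleles = {l: list(v) for l, v in genotype.alleles.items()}
    names = list(alleles)
    for _ in range(steps):
        l = names[rng.integers(len(names))]
        i = int(rng.integers(len(alleles[l])))
        alleles[l][i] += int(rng.choice([-1, 1])) * loci[l].motif_length
    return Genotype(
        individual_id=genotype.individual_id,
        population_id=genotype.population_id,
        ploidy=genotype.ploidy,
        alleles={l: tuple(sorted(v)) for l, v in alleles.items()},
        taxon_label=genotype.taxon_label,
    )


def simulate_genotypes(config: SimulationConfig):
    """Genotypes, Q-matrix and ground truth for the configured taxa.

    Pure individuals sample ploidy-many alleles per locus from their
    species' frequencies; hybrids combine gametes of both parents (the
    polyploid parent contributes the unreduced share of an odd-ploid
    hybrid); clones copy a founder genotype with at most the configured
    number of stepwise mutations.  Q-matrix rows are Dirichlet draws
    concentrated on the true ancestry vector.

    Returns ``(genotypes, loci, qmatrix, truth)`` where truth is a DataFrame
    with individual_id, taxon, subgroup, genet_id, ploidy and the true
    species-ancestry proportions.
    """
    rng = np.random.default_rng(config.seed)
    loci = _make_loci(config)
    freqs = _species_frequencies(config, loci, rng)
    clusters = [sub for sp in SPECIES for sub in SUBGROUPS[sp]]

    genotypes: list[Genotype] = []
    truth_rows = []
    q_rows = []

    for taxon, spec in config.taxa.items():
        ploidies = sorted(spec.ploidy)
        pl_probs = [spec.ploidy[p] for p in ploidies]
        # founders (distinct genets); clones replace the tail of the sample
        n_clonal_ramets = spec.clones.n_clones * (spec.clones.ramets_per_clone - 1)
        if n_clonal_ramets >= spec.n:
            raise ValueError(f"{taxon}: clone spec exceeds sample size")
        n_founders = spec.n - n_clonal_ramets

        founders: list[tuple[Genotype, str, np.ndarray]] = []
        for i in range(n_founders):
            ind = f"{taxon}_{i:03d}"
            ploidy = int(rng.choice(ploidies, p=pl_probs))
            ancestry = np.zeros(len(clusters))
            if taxon in SPECIES:
                sub = SUBGROUPS[taxon][int(rng.integers(len(SUBGROUPS[taxon])))]
                ancestry[clusters.index(sub)] = 1.0
                alleles = {
                    l: _draw_alleles(freqs[taxon][l], ploidy, rng) for l in loci
                }
            else:
                pa, pb = HYBRID_PARENTS[taxon]
                # the polyploid parent contributes the larger gamete
                poly = pb if max(config.taxa.get(pb, spec).ploidy or {2: 1}) >= \
                    max(config.taxa.get(pa, spec).ploidy or {2: 1}) else pa
                other = pa if poly == pb else pb
                k_poly = ploidy - ploidy // 2
                k_other = ploidy // 2
                alleles = {}
                for l in loci:
                    a = _draw_alleles(freqs[poly][l], k_poly, rng)
                    b = _draw_alleles(freqs[other][l], k_other, rng)
                    alleles[l] = tuple(sorted(a + b))
                sub_a = SUBGROUPS[pa][int(rng.integers(len(SUBGROUPS[pa])))]
                sub_b = SUBGROUPS[pb][int(rng.integers(len(SUBGROUPS[pb])))]
                ancestry[clusters.index(sub_a)] = 0.5
                ancestry[clusters.index(sub_b)] = 0.5
                sub = f"{sub_a}x{sub_b}"
            g = Genotype(ind, "pop1", ploidy,
                         {l: tuple(sorted(set(v))) for l, v in alleles.items()},
                         taxon_label=taxon)
            founders.append((g, sub, ancestry))
            genotypes.append(g)
            truth_rows.append(
                {"individual_id": ind, "taxon": taxon, "subgroup": sub,
                 "genet_id": ind, "ploidy": ploidy,
                 **{f"anc_{c}": ancestry[ci] for ci, c in enumerate(clusters)}}
            )
            q = rng.dirichlet(config.q_concentration * ancestry + 0.02)
            q_rows.append({"individual_id": ind,
                           **{c: q[ci] for ci, c in enumerate(clusters)}})

        # clones: copies of the first founders with a few stepwise mutations
        k = n_founders
        for ci in range(spec.clones.n_clones):
            founder, sub, ancestry = founders[ci % len(founders)]
            for _ in range(spec.clones.ramets_per_clone - 1):
                ind = f"{taxon}_{k:03d}"
                steps = int(rng.integers(0, spec.clones.max_mutation_steps + 1))
                ramet = _mutate(
                    Genotype(ind, founder.population_id, founder.ploidy,
                             dict(founder.alleles), taxon_label=taxon),
                    loci, steps, rng,
                )
                genotypes.append(ramet)
                truth_rows.append(
                    {"individual_id": ind, "taxon": taxon, "subgroup": sub,
                     "genet_id": founder.individual_id, "ploidy": founder.ploidy,
                     **{f"anc_{c}": ancestry[cj] for cj, c in enumerate(clusters)}}
                )
                q = rng.dirichlet(config.q_concentration * ancestry + 0.02)
                q_rows.append({"individual_id": ind,
                               **{c: q[cj] for cj, c in enumerate(clusters)}})
                k += 1

    truth = pd.DataFrame(truth_rows).set_index("individual_id")
    qmatrix = pd.DataFrame(q_rows).set_index("individual_id")
    return genotypes, loci, qmatrix, truth


# ---------------------------------------------------------------------------
# flow cytometry + seeds


_PATHWAYS = ("sexual", "pseudogamous", "autonomous")


def _draw_seed(m: int, pathway: str, rng: np.random.Generator):
    """Forward model of one seed: pathway -> (embryo, endosperm) ploidies."""
    if pathway == "sexual":
        egg = m / 2.0 if m % 2 == 0 else (1.5 if rng.random() < 0.8 else 1.0)
        sperm = int(rng.choice([1, 2], p=[0.85, 0.15]))
        return egg + sperm, 2 * egg + sperm, {"egg": egg, "sperm": sperm}
    if pathway == "autonomous":
        return float(m), float(2 * m), {"egg": m, "sperm": 0}
    if pathway == "pseudogamous":
        sn = int(rng.choice([1, 2, 3, 4], p=[0.6, 0.25, 0.1, 0.05]))
        return float(m), float(2 * m + sn), {"egg": m, "sperm": 0, "sperm_n": sn}
    raise ValueError(f"unknown pathway {pathway!r}")


def simulate_fcm_and_seeds(config: SimulationConfig, truth: pd.DataFrame):
    """Leaf FCM indices and a flow-cytometric seed screen.

    Leaf index ~ Normal(base * ploidy / 2, sd) against *Pisum*.  Seeds are
    drawn per mother from the taxon's pathway mixture; embryo and endosperm
    ploidies follow the forward pathway rules (sexual e = ♀+♂, n = 2♀+♂;
    pseudogamous e = m, n = 2m+♂n; autonomous e = m, n = 2m) and are
    converted to *Carex*-standard indices with multiplicative noise.

    Returns ``(fcm, seeds, seed_truth)`` DataFrames.
    """
    rng = np.random.default_rng(config.seed + 1)
    fs = config.fcm
    fcm_rows = []
    for ind, row in truth.iterrows():
        idx = rng.normal(fs.leaf_base_index * row["ploidy"] / 2.0, fs.leaf_sd)
        fcm_rows.append(
            {"sample_id": ind, "taxon": row["taxon"], "tissue": "leaf",
             "standard": "Pisum", "index": max(idx, 1e-6)}
        )
    fcm = pd.DataFrame(fcm_rows)

    seed_rows, truth_rows = [], []
    sid = 0
    for ind, row in truth.iterrows():
        spec = config.taxa[row["taxon"]]
        if not spec.reproduction:
            continue
        paths = sorted(spec.reproduction)
        probs = [spec.reproduction[p] for p in paths]
        m = int(row["ploidy"])
        for _ in range(fs.seeds_per_mother):
            pathway = str(rng.choice(paths, p=probs))
            e, n, parts = _draw_seed(m, pathway, rng)
            e_idx = fs.seed_base_index * e / 2.0 * (1 + rng.normal(0, fs.seed_rel_sd))
            n_idx = fs.seed_base_index * n / 2.0 * (1 + rng.normal(0, fs.seed_rel_sd))
            seed_rows.append(
                {"seed_id": f"seed_{sid:05d}", "mother_id": ind,
                 "taxon": row["taxon"], "maternal_ploidy": m,
                 "embryo_index": e_idx, "endosperm_index": n_idx,
                 "standard": "Carex"}
            )
            truth_rows.append(
                {"seed_id": f"seed_{sid:05d}", "pathway": pathway,
                 "embryo_ploidy": e, "endosperm_ploidy": n, **parts}
            )
            sid += 1
    return fcm, pd.DataFrame(seed_rows), pd.DataFrame(truth_rows).set_index("seed_id")


# ---------------------------------------------------------------------------
# morphology


def _leaf_template_base() -> np.ndarray:
    """A 13-landmark lobed-leaf scheme: petiole junction and lamina base at
    the bottom, apex at the top, paired basal/secondary lobes and sinuses."""
    return np.array([
        [0.00, -1.00],   # 1 petiole junction
        [0.00, -0.75],   # 2 lamina base
        [-0.28, -0.72],  # 3 initial serration, left basal lobe
        [-0.62, -0.45],  # 4 apex, left basal lobe
        [-0.25, -0.30],  # 5 left basal sinus
        [-0.48, 0.05],   # 6 apex, left second lobe
        [-0.20, 0.18],   # 7 left sinus after second lobe
        [0.00, 0.75],    # 8 leaf apex
        [0.20, 0.18],    # 9 right sinus after second lobe
        [0.48, 0.05],    # 10 apex, right second lobe
        [0.25, -0.30],   # 11 right basal sinus
        [0.62, -0.45],   # 12 apex, right basal lobe
        [0.28, -0.72],   # 13 initial serration, right basal lobe
    ])


def species_templates() -> dict[str, np.ndarray]:
    """Hand-built illustrative leaf templates (not digitized from specimens):
    a shallow-lobed form (L), a deep-lobed form (M) and an intermediate
    serrate form (R)."""
    base = _leaf_template_base()
    sinus = [2, 4, 6, 8, 10]   # indices (0-based) of sinus-like points 3,5,7,9,11
    lobes = [3, 5, 9, 11]      # lobe apices 4, 6, 10, 12

    shallow = base.copy()      # L: shallow lobes, broad blade
    shallow[sinus, 0] *= 1.55
    shallow[lobes, 0] *= 0.85
    shallow[7, 1] = 0.62

    deep = base.copy()         # M: deeply incised lobes
    deep[sinus, 0] *= 0.45
    deep[lobes, 0] *= 1.15
    deep[lobes, 1] -= 0.05

    serrate = base.copy()      # R: intermediate incision, acute basal lobes
    serrate[sinus, 0] *= 0.95
    serrate[[3, 11], 1] -= 0.18
    serrate[[2, 12], 0] *= 1.25

    return {"L": shallow, "M": deep, "R": serrate}


_FRUIT_TRAITS = ("DR", "L", "W", "WP", "SL", "SW")

_FRUIT_MEANS = {
    "L": {"DR": 2.4, "L": 9.0, "W": 8.2, "WP": 4.2, "SL": 2.6, "SW": 2.2},
    "M": {"DR": 2.0, "L": 10.0, "W": 9.0, "WP": 4.8, "SL": 2.2, "SW": 1.8},
    "R": {"DR": 1.6, "L": 12.5, "W": 9.5, "WP": 5.8, "SL": 3.4, "SW": 1.6},
}

_PYRENES = {"L": {2: 0.6, 3: 0.4}, "M": {1: 1.0}, "R": {1: 1.0}}


def _taxon_morph_params(taxon: str):
    templates = species_templates()
    if taxon in SPECIES:
        return templates[taxon], _FRUIT_MEANS[taxon], _PYRENES[taxon]
    pa, pb = HYBRID_PARENTS[taxon]
    tpl = 0.5 * (templates[pa] + templates[pb])
    means = {t: 0.5 * (_FRUIT_MEANS[pa][t] + _FRUIT_MEANS[pb][t])
             for t in _FRUIT_TRAITS}
    pyr = {}
    for src in (pa, pb):
        for count, p in _PYRENES[src].items():
            pyr[count] = pyr.get(count, 0.0) + 0.5 * p
    return tpl, means, pyr


def simulate_morphology(config: SimulationConfig, truth: pd.DataFrame):
    """Leaf landmark sets (both shoot types) and a fruit-trait table.

    Each individual's shape is its taxon template (hybrids: midpoint of the
    parent templates) plus an individual effect; each leaf adds isotropic
    landmark noise.  Short-shoot leaves use a slightly compressed variant of
    the template.  Fruit vectors are Gaussian around per-taxon means with
    the pyrene count drawn from a per-taxon categorical distribution.

    Returns ``(flowering_records, short_records, fruits, shape_truth)``;
    landmark records are TPS-style dicts with ids ``<individual>_fl<i>``.
    """
    rng = np.random.default_rng(config.seed + 2)
    ms = config.morphology
    fl_records, sh_records, fruit_rows, truth_rows = [], [], [], []
    for ind, row in truth.iterrows():
        taxon = row["taxon"]
        tpl, fruit_means, pyrene_dist = _taxon_morph_params(taxon)
        ind_sd = ms.individual_sd
        if taxon in HYBRID_PARENTS:
            ind_sd *= ms.hybrid_sd_scale
        ind_effect = rng.normal(0, ind_sd, size=tpl.shape)
        for shoot, records in (("fl", fl_records), ("sh", sh_records)):
            base = tpl + ind_effect
            if shoot == "sh":
                base = base * np.array([1.0, 0.92])  # short-shoot leaves squatter
            n_leaves = int(rng.integers(ms.leaves_per_shoot[0],
                                        ms.leaves_per_shoot[1] + 1))
            for li in range(n_leaves):
                coords = base + rng.normal(0, ms.leaf_sd, size=tpl.shape)
                # arbitrary digitization frame: random similarity transform
                theta = rng.uniform(0, 2 * np.pi)
                R = np.array([[np.cos(theta), -np.sin(theta)],
                              [np.sin(theta), np.cos(theta)]])
                scale = rng.uniform(40, 120)
                shift = rng.uniform(100, 900, size=2)
                records.append({"id": f"{ind}_{shoot}{li}",
                                "coords": coords @ R.T * scale + shift})
        fruit = {t: fruit_means[t] * (1 + rng.normal(0, ms.fruit_rel_sd))
                 for t in _FRUIT_TRAITS}
        counts = sorted(pyrene_dist)
        fruit["P"] = int(rng.choice(counts, p=[pyrene_dist[c] for c in counts]))
        fruit_rows.append({"individual_id": ind, "taxon": taxon, **fruit})
        truth_rows.append({"individual_id": ind, "taxon": taxon,
                           "template": taxon})
    fruits = pd.DataFrame(fruit_rows).set_index("individual_id")
    shape_truth = pd.DataFrame(truth_rows).set_index("individual_id")
    return fl_records, sh_records, fruits, shape_truth


def simulate_all(config: SimulationConfig):
    """Run all three generators and return a dict of datasets + ground truth."""
    genotypes, loci, qmatrix, truth = simulate_genotypes(config)
    fcm, seeds, seed_truth = simulate_fcm_and_seeds(config, truth)
    fl, sh, fruits, shape_truth = simulate_morphology(config, truth)
    return {
        "genotypes": genotypes,
        "loci": loci,
        "qmatrix": qmatrix,
        "truth": truth,
        "fcm": fcm,
        "seeds": seeds,
        "seed_truth": seed_truth,
        "leaves_fl": fl,
        "leaves_sh": sh,
        "fruits": fruits,
        "shape_truth": shape_truth,
    }
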