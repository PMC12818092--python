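"""Taxon calls from admixture proportions (Q-matrices), and the Evanno ΔK.

Bayesian clustering (run externally) yields per-individual assignment
proportions over K genetic clusters.  Clusters map to species-level groups —
here hawthorns: L (*C. laevigata*), M (*C. monogyna*), R (*C. rhipidophylla*)
— possibly with geographic subgroups (L1, L2, R1...).  An individual is:

* a **pure group** member if one species holds at least ``upper`` (default
  0.85) of its ancestry and one subgroup of that species does too;
* **intra-species admixed** (e.g. "L1 × L2") if the species is fixed but no
  single subgroup dominates;
* an **interspecific hybrid** if exactly two species each hold between
  ``lower`` and ``upper`` and jointly at least ``upper`` — named from the
  hybrid table (L×M = MED, L×R = MAC, M×R = SUB);
* **unresolved** otherwise (e.g. three-way admixture).

The 15%/85% bounds follow the convention that at most 15% foreign admixture
still counts as pure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClusterSpeciesMap",
    "TaxonCall",
    "classify_individual",
    "classify_qmatrix",
    "ternary_coordinates",
    "evanno_delta_k",
]


@dataclass(frozen=True)
class ClusterSpeciesMap:
    """Mapping cluster -> (species, subgroup) plus hybrid naming table."""

    clusters: Mapping[str, tuple[str, str]]
    hybrid_names: Mapping[frozenset, str]

    def __post_init__(self) -> None:
        species = {s for s, _ in self.clusters.values()}
        for a in species:
            for b in species:
                if a < b and frozenset({a, b}) not in self.hybrid_names:
                    raise ValueError(f"hybrid table missing pair {a} x {b}")

    def species_of(self, cluster: str) -> str:
        return self.clusters[cluster][0]

    def subgroup_of(self, cluster: str) -> str:
        return self.clusters[cluster][1]

    @classmethod
    def default_crataegus(cls) -> "ClusterSpeciesMap":
        """The six-cluster hawthorn layout: two *laevigata* subgroups, one
        *monogyna* group, three *rhipidophylla* subgroups."""
        return cls(
            clusters={
                "L1": ("L", "L1"),
                "L2": ("L", "L2"),
                "MON": ("M", "MON"),
                "R1": ("R", "R1"),
                "R2": ("R", "R2"),
                "R3": ("R", "R3"),
            },
            hybrid_names={
                frozenset({"L", "M"}): "MED",
                frozenset({"L", "R"}): "MAC",
                frozenset({"M", "R"}): "SUB",
            },
        )


@dataclass
class TaxonCall:
    """Outcome of the threshold classification for one individual."""

    category: str  # pure-group | intra-species-admixed | interspecific-hybrid | unresolved
    label: str
    species_props: dict[str, float] = field(default_factory=dict)


def classify_individual(
    q_row: Mapping[str, float],
    cmap: ClusterSpeciesMap,
    lower: float = 0.15,
    upper: float = 0.85,
) -> TaxonCall:
    """Classify one Q-matrix row.

    Thresholds are applied at the species level first, then at the subgroup
    level, which reproduces the coexistence of pure-subgroup, within-species
    admixed, and interspecific-hybrid calls.  Boundary values are inclusive
    (a proportion of exactly ``upper`` counts as pure).
    """
    total = float(sum(q_row.values()))
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"Q-matrix row sums to {total}, expected 1")
    unknown = set(q_row) - set(cmap.clusters)
    if unknown:
        raise ValueError(f"clusters not in map: {sorted(unknown)}")

    species_props: dict[str, float] = {}
    for cluster, p in q_row.items():
        species_props[cmap.species_of(cluster)] = (
            species_props.get(cmap.species_of(cluster), 0.0) + float(p)
        )

    top_species = max(species_props, key=species_props.get)
    if species_props[top_species] >= upper:
        sub = {
            cmap.subgroup_of(c): float(p)
            for c, p in q_row.items()
            if cmap.species_of(c) == top_species
        }
        top_sub = max(sub, key=sub.get)
        if sub[top_sub] >= upper:
            return TaxonCall("pure-group", top_sub, species_props)
        contributors = sorted(
            (s for s, p in sub.items() if p >= lower),
            key=lambda s: -sub[s],
        )
        if len(contributors) < 2:
            contributors = sorted(sub, key=lambda s: -sub[s])[:2]
        return TaxonCall("intra-species-admixed", " × ".join(contributors), species_props)

    mid = [s for s, p in species_props.items() if lower <= p <= upper]
    if len(mid) == 2 and sum(species_props[s] for s in mid) >= upper:
        name = cmap.hybrid_names[frozenset(mid)]
        return TaxonCall("interspecific-hybrid", name, species_props)
    return TaxonCall("unresolved", "unresolved", species_props)


def classify_qmatrix(
    qmatrix: pd.DataFrame,
    cmap: ClusterSpeciesMap,
    lower: float = 0.15,
    upper: float = 0.85,
) -> pd.DataFrame:
    """Classify every row of a Q-matrix (index = individual ids)."""
    rows = []
    for ind, row in qmatrix.iterrows():
        call = classify_individual(row.to_dict(), cmap, lower=lower, upper=upper)
        rec = {"individual_id": ind, "category": call.category, "label": call.label}
        rec.update({f"p_{s}": v for s, v in sorted(call.species_props.items())})
        rows.append(rec)
    return pd.DataFrame(rows).set_index("individual_id")


def ternary_coordinates(species_props: Sequence[float]) -> tuple[float, float]:
    """Barycentric embedding of three proportions into the unit triangle.

    Vertices: first species at (0, 0), second at (1, 0), third at
    (0.5, sqrt(3)/2); the centroid (1/3, 1/3, 1/3) maps to (0.5, sqrt(3)/6).
    """
    p = [float(x) for x in species_props]
    if len(p) != 3:
        raise ValueError("need exactly three proportions")
    if any(x < 0 for x in p):
        raise ValueError("proportions must be non-negative")
    if abs(sum(p) - 1.0) > 1e-6:
        raise ValueError("proportions must sum to 1")
    x = p[1] + 0.5 * p[2]
    y = (sqrt(3) / 2.0) * p[2]
    return (x, y)


def evanno_delta_k(table: pd.DataFrame) -> pd.Series:
    """Evanno ΔK for each interior K.

    ``table`` columns: ``K``, ``mean_lnP`` (mean log-likelihood over replicate
    runs), ``sd_lnP`` (their standard deviation).  ΔK(K) =
    |L(K+1) - 2·L(K) + L(K-1)| / sd(K); the K with the greatest ΔK is the
    conventional cluster-number choice.
    """
    t = table.sort_values("K").reset_index(drop=True)
    if len(t) < 3:
        raise ValueError("need at least three consecutive K values")
    ks = t["K"].to_numpy()
    if not np.all(np.diff(ks) == 1):
        raise ValueError("K values must be consecutive")
    L = t["mean_lnP"].to_numpy(dtype=float)
    sd = t["sd_lnP"].to_numpy(dtype=float)
    out = {}
    for i in range(1, len(t) - 1):
        if sd[i] <= 0:
            raise ValueError(
                f"sd(K={ks[i]}) is zero: replicate runs are degenerate"
            )
        out[int(ks[i])] = abs(L[i + 1] - 2 * L[i] + L[i - 1]) / sd[i]
    return pd.Series(out, name="delta_K")
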