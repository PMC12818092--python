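"""Polyploid microsatellite genotypes: distances, clones, dosage, ordination.

Microsatellite (nuSSR) alleles are scored as fragment sizes in base pairs.
Under the stepwise mutation model a mutation adds or removes one repeat
motif, so distances between alleles are naturally expressed in repeat units
(``size_bp / motif_length``).  Two genotype-level distances are provided:

* the **stepwise distance** — the smallest total number of repeat-unit
  mutation steps needed to transform one genotype into the other, summed
  over loci; used with a histogram-derived threshold to collapse clonal
  ramets into genets;
* the **Bruvo distance** — per allele pair ``1 - 2**(-|dr|)`` where ``dr``
  is the repeat-count difference, averaged over the optimal allele matching
  and over loci; bounded in [0, 1] and robust to mixed ploidy, hence used
  for ordination (PCoA).

Polyploid genotypes are often scored with unknown allele dosage (each
distinct allele recorded once); :func:`restore_dosage` completes them to
full ploidy by maximum multinomial likelihood under iteratively re-estimated
population allele frequencies.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from math import factorial
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import gaussian_kde

from .util import round_half_up

__all__ = [
    "Locus",
    "Genotype",
    "DistanceMatrix",
    "ClonalAssignment",
    "PCoAResult",
    "size_to_repeats",
    "stepwise_distance",
    "bruvo_distance",
    "pairwise_distance_matrix",
    "suggest_clone_threshold",
    "detect_clones",
    "summarize_clonality",
    "restore_dosage",
    "pcoa",
]

DEFAULT_SIZE_WINDOW = (100, 500)


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus: a name, its repeat-motif length in bp, and the
    allele-size window retained during scoring."""

    name: str
    motif_length: int
    size_window: tuple[int, int] = DEFAULT_SIZE_WINDOW

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"locus {self.name}: motif_length must be >= 1")
        lo, hi = self.size_window
        if lo >= hi:
            raise ValueError(f"locus {self.name}: empty size window {self.size_window}")


@dataclass
class Genotype:
    """One individual's multilocus genotype.

    ``alleles`` maps locus name to a sorted tuple of allele sizes in bp.
    Before dosage restoration polyploid loci may hold fewer entries than the
    ploidy (each distinct allele recorded once); afterwards every scored
    locus holds exactly ``ploidy`` entries.  Missing loci are simply absent.
    """

    individual_id: str
    population_id: str
    ploidy: int
    alleles: dict[str, tuple[int, ...]]
    taxon_label: str | None = None

    def __post_init__(self) -> None:
        if not 2 <= self.ploidy <= 4:
            raise ValueError(
                f"{self.individual_id}: ploidy must be 2-4, got {self.ploidy}"
            )
        clean = {}
        for locus, sizes in self.alleles.items():
            tup = tuple(sorted(int(s) for s in sizes))
            if not tup:
                continue
            if len(set(tup)) > self.ploidy:
                raise ValueError(
                    f"{self.individual_id}/{locus}: {len(set(tup))} distinct alleles "
                    f"exceed ploidy {self.ploidy}"
                )
            if len(tup) > self.ploidy:
                raise ValueError(
                    f"{self.individual_id}/{locus}: more alleles than ploidy"
                )
            clean[locus] = tup
        self.alleles = clean

    def shared_loci(self, other: "Genotype") -> list[str]:
        return sorted(set(self.alleles) & set(other.alleles))


@dataclass
class DistanceMatrix:
    """Square symmetric pairwise distance matrix with a metric tag."""

    ids: list[str]
    values: np.ndarray
    metric: str
    flagged_pairs: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances as a flat vector."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class ClonalAssignment:
    """Genet membership for each sampled individual (ramet)."""

    ids: list[str]
    genet_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.genet_ids):
            raise ValueError("ids and genet_ids must be parallel")

    @property
    def genets(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for ind, gen in zip(self.ids, self.genet_ids):
            out.setdefault(gen, []).append(ind)
        return out

    @property
    def n_genets(self) -> int:
        return len(set(self.genet_ids))

    def partition(self) -> set[frozenset]:
        """Order-free view of the grouping (for comparisons)."""
        return {frozenset(m) for m in self.genets.values()}


# ---------------------------------------------------------------------------
# repeat-unit arithmetic


def size_to_repeats(size_bp: float, locus: Locus) -> float:
    """Convert an allele size in bp to a (possibly fractional) repeat count."""
    if size_bp <= 0:
        raise ValueError("allele size must be positive")
    if locus.motif_length < 1:
        raise ValueError("motif length must be >= 1")
    return size_bp / locus.motif_length


def _repeats(genotype: Genotype, locus: Locus) -> list[float]:
    return [size_to_repeats(s, locus) for s in genotype.alleles[locus.name]]


# ---------------------------------------------------------------------------
# stepwise distance


def _stepwise_locus(r1: Sequence[float], r2: Sequence[float]) -> float:
    """Minimal total |repeat difference| between two allele multisets.

    Equal counts: optimal one-to-one assignment.  Unequal counts: the smaller
    multiset is assigned optimally into the larger; every unmatched allele of
    the larger multiset contributes its distance to the nearest allele of the
    smaller one.
    """
    a = np.asarray(sorted(r1), dtype=float)
    b = np.asarray(sorted(r2), dtype=float)
    if len(a) > len(b):
        a, b = b, a
    cost = np.abs(a[:, None] - b[None, :])
    # every unmatched large allele j costs its nearest-allele distance c_j;
    # minimizing (matched cost + unmatched c_j) jointly is an assignment on
    # the reduced costs |a_i - b_j| - c_j plus the constant sum of c_j
    c = cost.min(axis=0)
    reduced = cost - c[None, :]
    rows, cols = linear_sum_assignment(reduced)
    return float(c.sum() + reduced[rows, cols].sum())


def stepwise_distance(
    g1: Genotype, g2: Genotype, loci: Mapping[str, Locus]
) -> float:
    """Smallest number of repeat-unit mutation steps between two genotypes,
    summed over shared loci (missing loci skipped)."""
    shared = g1.shared_loci(g2)
    if not shared:
        raise ValueError(
            f"no shared loci between {g1.individual_id} and {g2.individual_id}"
        )
    return float(
        sum(_stepwise_locus(_repeats(g1, loci[l]), _repeats(g2, loci[l])) for l in shared)
    )


# ---------------------------------------------------------------------------
# Bruvo distance


def _bruvo_pair(x: float, y: float) -> float:
    return 1.0 - 2.0 ** (-abs(x - y))


def _min_mean_matching(a: Sequence[float], b: Sequence[float]) -> float:
    """Minimal mean per-allele Bruvo distance over one-to-one matchings."""
    k = len(a)
    cost = np.array([[_bruvo_pair(x, y) for y in b] for x in a])
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum() / k)


def _bruvo_locus(r1: Sequence[float], r2: Sequence[float]) -> float:
    """Per-locus Bruvo distance.

    Equal allele counts: optimal matching.  Unequal counts (mixed ploidy or
    unrestored dosage): average of the genome-addition model (the smaller
    genotype is filled with copies of its own alleles) and the genome-loss
    model (filled with alleles of the larger genotype), each averaged over
    every possible fill, with the optimal matching inside each fill.
    """
    if len(r1) == len(r2):
        return _min_mean_matching(r1, r2)
    small, large = (r1, r2) if len(r1) < len(r2) else (r2, r1)
    deficit = len(large) - len(small)

    def model(candidates: Sequence[float]) -> float:
        fills = itertools.combinations_with_replacement(sorted(set(candidates)), deficit)
        vals = [_min_mean_matching(list(small) + list(f), large) for f in fills]
        return float(np.mean(vals))

    return 0.5 * (model(small) + model(large))


def bruvo_distance(g1: Genotype, g2: Genotype, loci: Mapping[str, Locus]) -> float:
    """Bruvo distance in [0, 1]: mean per-locus distance over shared loci."""
    shared = g1.shared_loci(g2)
    if not shared:
        raise ValueError(
            f"no shared loci between {g1.individual_id} and {g2.individual_id}"
        )
    vals = [_bruvo_locus(_repeats(g1, loci[l]), _repeats(g2, loci[l])) for l in shared]
    return float(np.mean(vals))


_METRICS = {"stepwise": stepwise_distance, "bruvo": bruvo_distance}


def pairwise_distance_matrix(
    genotypes: Sequence[Genotype],
    loci: Mapping[str, Locus],
    metric: str = "bruvo",
    min_shared_loci: int = 10,
) -> DistanceMatrix:
    """All-pairs distance matrix.

    Pairs sharing fewer than ``min_shared_loci`` loci are still computed but
    flagged (``flagged_pairs``) so downstream users can drop or inspect them.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes")
    fn = _METRICS[metric]
    n = len(genotypes)
    values = np.zeros((n, n))
    flagged: list[tuple[str, str, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = genotypes[i], genotypes[j]
            n_shared = len(gi.shared_loci(gj))
            d = fn(gi, gj, loci)
            values[i, j] = values[j, i] = d
            if n_shared < min_shared_loci:
                flagged.append((gi.individual_id, gj.individual_id, n_shared))
    return DistanceMatrix(
        ids=[g.individual_id for g in genotypes],
        values=values,
        metric=metric,
        flagged_pairs=flagged,
    )


# ---------------------------------------------------------------------------
# clone detection


def suggest_clone_threshold(
    distance_values: Iterable[float], grid_points: int = 512
) -> float | None:
    """Threshold separating the near-zero clonal mode from the main mode.

    A Gaussian kernel density (Silverman bandwidth) is fitted to the pairwise
    distances and the first interior local minimum between the first two
    density modes is returned.  For a unimodal distribution there is no
    valley; ``None`` is returned with a warning and the caller should supply
    a threshold (the study default is 22 mutation steps).
    """
    v = np.asarray(list(distance_values), dtype=float)
    if v.size == 0:
        raise ValueError("no distances supplied")
    if v.size < 10:
        raise ValueError("need at least 10 pairwise distances to locate a valley")
    if np.ptp(v) == 0:
        warnings.warn("all distances identical; no valley found", stacklevel=2)
        return None
    kde = gaussian_kde(v, bw_method="silverman")
    grid = np.linspace(v.min(), v.max(), grid_points)
    dens = kde(grid)
    d = np.diff(dens)
    maxima = [i for i in range(1, len(dens) - 1) if d[i - 1] > 0 >= d[i]]
    minima = [i for i in range(1, len(dens) - 1) if d[i - 1] < 0 <= d[i]]
    if len(maxima) < 2:
        warnings.warn("distance distribution appears unimodal; no threshold suggested",
                      stacklevel=2)
        return None
    first_valley = next((i for i in minima if maxima[0] < i < maxima[-1]), None)
    if first_valley is None:
        warnings.warn("no interior valley between modes", stacklevel=2)
        return None
    return float(grid[first_valley])


def detect_clones(dist: DistanceMatrix, threshold: float) -> ClonalAssignment:
    """Single-linkage clone grouping.

    Two ramets belong to the same genet iff they are connected by a chain of
    pairwise distances <= ``threshold``.  Each genet is labelled by its first
    member in input order (labels are representatives; the grouping itself is
    order-invariant).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    adj = dist.values <= threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    reps: dict[int, str] = {}
    genet_ids = []
    for ind, lab in zip(dist.ids, labels):
        reps.setdefault(lab, ind)
        genet_ids.append(reps[lab])
    return ClonalAssignment(ids=list(dist.ids), genet_ids=genet_ids)


def summarize_clonality(
    assignment: ClonalAssignment, group_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group clonality table.

    For every group (species, hybrid class, population...): the number of
    sampled ramets, distinct genets, genets with >= 2 members, and the
    clonality percentage = 100 x (ramets in multi-member genets) / ramets,
    rounded half-up to one decimal.
    """
    missing = [i for i in assignment.ids if i not in group_labels]
    if missing:
        raise ValueError(f"unlabeled individuals: {missing[:5]}")
    rows = []
    by_group: dict[str, list[str]] = {}
    genet_of = dict(zip(assignment.ids, assignment.genet_ids))
    for ind in assignment.ids:
        by_group.setdefault(group_labels[ind], []).append(ind)
    for group in sorted(by_group):
        members = by_group[group]
        counts = Counter(genet_of[i] for i in members)
        n_ramets = len(members)
        n_genets = len(counts)
        clonal = {g: c for g, c in counts.items() if c >= 2}
        clonal_ramets = sum(clonal.values())
        rows.append(
            {
                "group": group,
                "n_ramets": n_ramets,
                "n_genets": n_genets,
                "n_clonal_genets": len(clonal),
                "clonality_pct": round_half_up(100.0 * clonal_ramets / n_ramets, 1),
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# dosage restoration


def _multinomial_logprob(counts: Counter, freqs: Mapping[int, float]) -> float:
    n = sum(counts.values())
    coef = factorial(n)
    lp = 0.0
    for allele, c in counts.items():
        coef //= factorial(c)
        f = freqs.get(allele, 1e-12)
        lp += c * np.log(max(f, 1e-300))
    return float(np.log(coef) + lp)


def _best_completion(
    observed: tuple[int, ...], ploidy: int, freqs: Mapping[int, float]
) -> tuple[int, ...]:
    distinct = tuple(sorted(set(observed)))
    deficit = ploidy - len(observed)
    best, best_lp = None, -np.inf
    for extra in itertools.combinations_with_replacement(distinct, deficit):
        counts = Counter(observed) + Counter(extra)
        lp = _multinomial_logprob(counts, freqs)
        cand = tuple(sorted(counts.elements()))
        if lp > best_lp or (lp == best_lp and (best is None or cand < best)):
            best, best_lp = cand, lp
    assert best is not None
    return best


def restore_dosage(
    genotypes: Sequence[Genotype], max_iter: int = 50
) -> list[Genotype]:
    """Complete under-filled polyploid loci to full ploidy.

    Within each population, allele frequencies are estimated from the current
    dosage assignment; each under-filled locus is then completed with the
    extra copies that maximize the multinomial probability of the genotype,
    and frequencies are re-estimated, iterating to a fixed point (at most
    ``max_iter`` sweeps).  Already-full loci are left untouched.
    """
    current = {g.individual_id: dict(g.alleles) for g in genotypes}
    by_pop: dict[str, list[Genotype]] = {}
    for g in genotypes:
        by_pop.setdefault(g.population_id, []).append(g)

    for pop, members in by_pop.items():
        loci_names = sorted({l for g in members for l in g.alleles})
        for _ in range(max_iter):
            changed = False
            # frequencies from the current (possibly partial) assignment
            freqs: dict[str, dict[int, float]] = {}
            for l in loci_names:
                cnt: Counter = Counter()
                for g in members:
                    cnt.update(current[g.individual_id].get(l, ()))
                total = sum(cnt.values())
                freqs[l] = {a: c / total for a, c in cnt.items()} if total else {}
            for g in members:
                for l, sizes in list(current[g.individual_id].items()):
                    if len(sizes) < g.ploidy:
                        new = _best_completion(sizes, g.ploidy, freqs[l])
                        if new != sizes:
                            current[g.individual_id][l] = new
                            changed = True
            if not changed:
                break

    out = []
    for g in genotypes:
        # re-fill any locus still short (first pass completes from observed
        # alleles, so every locus is already at full ploidy here)
        out.append(replace(g, alleles=dict(current[g.individual_id])))
    return out


# ---------------------------------------------------------------------------
# principal coordinates


@dataclass
class PCoAResult:
    """Metric ordination of a distance matrix (Gower double-centering)."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    pct_variance: np.ndarray


def pcoa(dist: DistanceMatrix | np.ndarray, n_axes: int | None = None,
         ids: Sequence[str] | None = None) -> PCoAResult:
    """Principal coordinates analysis.

    Double-centers ``-0.5 * d**2`` (Gower), eigen-decomposes, and returns
    coordinates on axes with positive eigenvalues, ordered by eigenvalue.
    Negative eigenvalues (non-Euclidean input) are reported unmodified;
    percentage variance uses positive eigenvalues only.
    """
    if isinstance(dist, DistanceMatrix):
        D = dist.values
        ids = dist.ids
    else:
        D = np.asarray(dist, dtype=float)
        if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("input must be a square symmetric matrix")
        ids = list(ids) if ids is not None else [str(i) for i in range(D.shape[0])]
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(1.0, float(np.abs(eigvals).max(initial=1.0)))
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    if n_axes is not None:
        if coords.shape[1] < n_axes:
            coords = np.hstack([coords, np.zeros((n, n_axes - coords.shape[1]))])
        coords = coords[:, :n_axes]
    pct = 100.0 * eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=list(ids), columns=cols),
        eigenvalues=eigvals,
        pct_variance=pct,
    )
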