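"""Distances, clone detection, dosage restoration and PCoA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crataegus.genotypes import (
    ClonalAssignment,
    DistanceMatrix,
    Genotype,
    Locus,
    bruvo_distance,
    detect_clones,
    pairwise_distance_matrix,
    pcoa,
    restore_dosage,
    size_to_repeats,
    stepwise_distance,
    suggest_clone_threshold,
    summarize_clonality,
)

# ---------------------------------------------------------------------------
# independent oracles


def brute_stepwise_locus(a, b):
    """Minimal total |Δrepeats| over all matchings (exhaustive)."""
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    best = np.inf
    for perm in itertools.permutations(range(len(large)), len(small)):
        cost = sum(abs(small[i] - large[j]) for i, j in enumerate(perm))
        unmatched = set(range(len(large))) - set(perm)
        cost += sum(min(abs(large[j] - s) for s in small) for j in unmatched)
        best = min(best, cost)
    return best


def brute_bruvo_equal(a, b):
    """Minimal mean per-allele Bruvo distance over all permutations."""
    k = len(a)
    best = np.inf
    for perm in itertools.permutations(range(k)):
        cost = sum(1 - 2.0 ** (-abs(float(a[i]) - float(b[j])))
                   for i, j in enumerate(perm)) / k
        best = min(best, cost)
    return best


def unit_genotype(ind, repeats, ploidy=2):
    """Genotype on motif-1 loci where sizes are repeat counts directly."""
    return Genotype(ind, "pop1", ploidy,
                    {l: tuple(v) for l, v in repeats.items()})


# ---------------------------------------------------------------------------
# size_to_repeats


@pytest.mark.parametrize(
    "size,motif,expected",
    [(100, 2, 50.0), (300, 3, 100.0), (101, 2, 50.5)],
)
def test_size_to_repeats(size, motif, expected):
    assert size_to_repeats(size, Locus("l", motif)) == expected


def test_size_to_repeats_rejects_nonpositive():
    with pytest.raises(ValueError):
        size_to_repeats(0, Locus("l", 2))


# ---------------------------------------------------------------------------
# stepwise distance


def test_stepwise_identical_is_zero(dinucleotide_locus):
    loci = {"locA": dinucleotide_locus}
    g = Genotype("i1", "p", 2, {"locA": (100, 104)})
    h = Genotype("i2", "p", 2, {"locA": (100, 104)})
    assert stepwise_distance(g, h, loci) == 0.0


def test_stepwise_optimal_pairing(dinucleotide_locus):
    # {100,104} vs {100,106} on a 2 bp motif: pair 100-100 and 104-106 -> 1 step
    loci = {"locA": dinucleotide_locus}
    g = Genotype("i1", "p", 2, {"locA": (100, 104)})
    h = Genotype("i2", "p", 2, {"locA": (100, 106)})
    assert stepwise_distance(g, h, loci) == 1.0


def test_stepwise_additive_over_loci(unit_loci):
    g = unit_genotype("i1", {"a": (50, 52), "b": (30, 31)})
    h = unit_genotype("i2", {"a": (50, 53), "b": (30, 32)})
    assert stepwise_distance(g, h, unit_loci) == pytest.approx(2.0)


def test_stepwise_no_shared_loci_errors(unit_loci):
    g = unit_genotype("i1", {"a": (50, 52)})
    h = unit_genotype("i2", {"b": (30, 31)})
    with pytest.raises(ValueError, match="shared"):
        stepwise_distance(g, h, unit_loci)


def test_stepwise_matches_bruteforce_on_random_multisets(rng):
    loci = {"a": Locus("a", 1)}
    for _ in range(200):
        ka, kb = rng.integers(1, 5, size=2)
        a = tuple(sorted(rng.integers(20, 40, size=ka)))
        b = tuple(sorted(rng.integers(20, 40, size=kb)))
        g = Genotype("i1", "p", 4, {"a": tuple(sorted(set(a)))})
        h = Genotype("i2", "p", 4, {"a": tuple(sorted(set(b)))})
        expected = brute_stepwise_locus(sorted(set(a)), sorted(set(b)))
        assert stepwise_distance(g, h, loci) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Bruvo distance


def test_bruvo_equal_single_alleles(unit_loci):
    g = unit_genotype("i1", {"a": (50,)})
    h = unit_genotype("i2", {"a": (50,)})
    assert bruvo_distance(g, h, unit_loci) == 0.0


def test_bruvo_one_step_is_half(unit_loci):
    g = unit_genotype("i1", {"a": (50,)})
    h = unit_genotype("i2", {"a": (51,)})
    assert bruvo_distance(g, h, unit_loci) == pytest.approx(0.5)


def test_bruvo_optimal_matching(unit_loci):
    # {20,23} vs {20,24}: match 20-20 (0) and 23-24 (0.5), mean 0.25
    g = unit_genotype("i1", {"a": (20, 23)})
    h = unit_genotype("i2", {"a": (20, 24)})
    assert bruvo_distance(g, h, unit_loci) == pytest.approx(0.25)


def test_bruvo_unequal_counts_combined_model(unit_loci):
    # {20} vs {20,21}: addition model fills 20 -> mean((0+0.5)/2)=0.25;
    # loss model fills with 20 (0.25) or 21 (0.0) -> 0.125; combined 0.1875
    g = unit_genotype("i1", {"a": (20,)})
    h = unit_genotype("i2", {"a": (20, 21)})
    assert bruvo_distance(g, h, unit_loci) == pytest.approx(0.1875)


def test_bruvo_bounded_and_matches_bruteforce_for_equal_counts(rng):
    loci = {"a": Locus("a", 1)}
    for _ in range(200):
        k = int(rng.integers(1, 5))
        a = tuple(sorted(rng.choice(np.arange(20, 40), size=k, replace=False)))
        b = tuple(sorted(rng.choice(np.arange(20, 40), size=k, replace=False)))
        g = Genotype("i1", "p", 4, {"a": a})
        h = Genotype("i2", "p", 4, {"a": b})
        d = bruvo_distance(g, h, loci)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(brute_bruvo_equal(a, b))


def test_metric_axioms_on_random_genotypes(rng):
    loci = {f"l{i}": Locus(f"l{i}", 1) for i in range(3)}
    gts = [
        Genotype(f"i{j}", "p", 2,
                 {l: tuple(sorted(rng.choice(np.arange(30, 40), 2,
                                             replace=False)))
                  for l in loci})
        for j in range(6)
    ]
    for metric in (stepwise_distance, bruvo_distance):
        for g, h in itertools.combinations(gts, 2):
            assert metric(g, h, loci) == pytest.approx(metric(h, g, loci))
            assert metric(g, h, loci) >= 0
        for g in gts:
            assert metric(g, g, loci) == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# pairwise matrix


def test_pairwise_matrix_matches_elementwise(unit_loci):
    gts = [
        unit_genotype("i1", {"a": (50, 52), "b": (30, 31)}),
        unit_genotype("i2", {"a": (50, 53), "b": (30, 32)}),
        unit_genotype("i3", {"a": (55, 56), "b": (35, 36)}),
    ]
    m = pairwise_distance_matrix(gts, unit_loci, metric="stepwise",
                                 min_shared_loci=1)
    assert np.allclose(m.values, m.values.T)
    assert np.all(np.diag(m.values) == 0)
    for i, j in itertools.combinations(range(3), 2):
        assert m.values[i, j] == pytest.approx(
            stepwise_distance(gts[i], gts[j], unit_loci)
        )


def test_pairwise_matrix_unknown_metric(unit_loci):
    gts = [unit_genotype("i1", {"a": (50,)}), unit_genotype("i2", {"a": (51,)})]
    with pytest.raises(ValueError, match="metric"):
        pairwise_distance_matrix(gts, unit_loci, metric="euclid")


def test_pairwise_matrix_flags_low_shared_loci(unit_loci):
    gts = [
        unit_genotype("i1", {"a": (50, 52)}),
        unit_genotype("i2", {"a": (50, 53), "b": (30, 31)}),
    ]
    m = pairwise_distance_matrix(gts, unit_loci, metric="stepwise",
                                 min_shared_loci=2)
    assert m.flagged_pairs == [("i1", "i2", 1)]


# ---------------------------------------------------------------------------
# clone threshold and detection


def test_threshold_found_in_gap_of_bimodal_sample(rng):
    low = rng.normal(5, 2, size=150).clip(0)
    high = rng.normal(70, 8, size=350)
    thr = suggest_clone_threshold(np.concatenate([low, high]))
    assert 15 < thr < 50


def test_threshold_none_for_unimodal_sample():
    local = np.random.default_rng(0)
    with pytest.warns(UserWarning, match="unimodal"):
        assert suggest_clone_threshold(local.normal(50, 5, size=300)) is None


def test_zero_distance_pairs_share_genet():
    vals = np.array([[0, 0, 80], [0, 0, 80], [80, 80, 0]], dtype=float)
    dist = DistanceMatrix(["a", "b", "c"], vals, "stepwise")
    a = detect_clones(dist, 22)
    assert a.genet_ids[0] == a.genet_ids[1] != a.genet_ids[2]


def test_all_distances_above_threshold_gives_all_singletons():
    vals = np.full((4, 4), 60.0)
    np.fill_diagonal(vals, 0.0)
    dist = DistanceMatrix(list("abcd"), vals, "stepwise")
    assert detect_clones(dist, 22).n_genets == 4


def test_detect_clones_partition_invariant_to_order(rng):
    n = 12
    base = rng.integers(0, 3, size=n)  # three planted genets
    vals = np.where(base[:, None] == base[None, :], 5.0, 80.0)
    np.fill_diagonal(vals, 0.0)
    ids = [f"i{k}" for k in range(n)]
    a1 = detect_clones(DistanceMatrix(ids, vals, "stepwise"), 22)
    perm = rng.permutation(n)
    a2 = detect_clones(
        DistanceMatrix([ids[p] for p in perm], vals[np.ix_(perm, perm)],
                       "stepwise"), 22)
    assert a1.partition() == a2.partition()


def test_negative_threshold_rejected():
    dist = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]), "stepwise")
    with pytest.raises(ValueError):
        detect_clones(dist, -1)


# ---------------------------------------------------------------------------
# clonality summary


def test_clonality_percentages_match_published_arithmetic():
    # 62 of 71 ramets in multi-member genets -> 87.3 %; 43 of 57 -> 75.4 %
    ids, genets, labels = [], [], {}
    # group R: 20 genets, 11 clonal covering 62 ramets, 9 singletons
    k = 0
    for gi, size in enumerate([6] * 7 + [5] * 4):
        for _ in range(size):
            ids.append(f"r{k}"); genets.append(f"Rg{gi}"); labels[f"r{k}"] = "R"; k += 1
    for _ in range(9):
        ids.append(f"r{k}"); genets.append(f"r{k}"); labels[f"r{k}"] = "R"; k += 1
    # group MAC: 43 clonal ramets of 57
    k = 0
    for gi, size in enumerate([4] * 10 + [3]):
        for _ in range(size):
            ids.append(f"m{k}"); genets.append(f"Mg{gi}"); labels[f"m{k}"] = "MAC"; k += 1
    for _ in range(14):
        ids.append(f"m{k}"); genets.append(f"m{k}"); labels[f"m{k}"] = "MAC"; k += 1
    summary = summarize_clonality(ClonalAssignment(ids, genets), labels)
    assert summary.loc["R", "n_ramets"] == 71
    assert summary.loc["R", "clonality_pct"] == 87.3
    assert summary.loc["MAC", "clonality_pct"] == 75.4


def test_clonality_zero_for_all_singletons():
    ids = [f"i{k}" for k in range(5)]
    s = summarize_clonality(ClonalAssignment(ids, list(ids)),
                            {i: "G" for i in ids})
    assert s.loc["G", "clonality_pct"] == 0.0
    assert s.loc["G", "n_genets"] == 5


def test_clonality_requires_labels():
    with pytest.raises(ValueError, match="unlabeled"):
        summarize_clonality(ClonalAssignment(["a"], ["a"]), {})


# ---------------------------------------------------------------------------
# dosage restoration


def test_restore_diploid_single_allele_duplicates():
    g = Genotype("i1", "p", 2, {"a": (140,)})
    (r,) = restore_dosage([g])
    assert r.alleles["a"] == (140, 140)


def test_restore_triploid_prefers_frequent_allele():
    # population dominated by allele 100: completion {100,100,104} beats
    # {100,104,104} (multinomial probabilities 3*f_a^2*f_b vs 3*f_a*f_b^2)
    pop = [Genotype(f"f{k}", "p", 3, {"a": (100, 100, 100)}) for k in range(8)]
    target = Genotype("t", "p", 3, {"a": (100, 104)})
    restored = restore_dosage(pop + [target])
    assert restored[-1].alleles["a"] == (100, 100, 104)


def test_restore_leaves_full_locus_unchanged():
    g = Genotype("i1", "p", 2, {"a": (100, 104)})
    (r,) = restore_dosage([g])
    assert r.alleles["a"] == (100, 104)


def test_restore_fills_every_locus_to_ploidy(rng):
    gts = []
    for k in range(10):
        alleles = {
            f"l{j}": tuple(sorted(set(rng.choice([100, 102, 104], size=3))))
            for j in range(4)
        }
        gts.append(Genotype(f"i{k}", "p", 3, alleles))
    for r in restore_dosage(gts):
        for sizes in r.alleles.values():
            assert len(sizes) == r.ploidy


# ---------------------------------------------------------------------------
# PCoA


def _euclidean_dm(points):
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    return d


def test_pcoa_recovers_line_geometry():
    pts = np.array([[0.0], [1.0], [3.0], [6.0]])
    res = pcoa(_euclidean_dm(pts), n_axes=1)
    axis = res.coordinates.iloc[:, 0].to_numpy()
    gaps = np.diff(np.sort(axis))
    assert np.allclose(sorted(gaps), sorted(np.diff(pts.ravel())), atol=1e-8)


def test_pcoa_zero_distances_give_zero_coordinates():
    res = pcoa(np.zeros((4, 4)), n_axes=2)
    assert np.allclose(res.coordinates.to_numpy(), 0.0)


def test_pcoa_equals_pca_up_to_orthogonal_transform(rng):
    # PCoA of Euclidean distances reproduces centered coordinates up to
    # rotation/reflection (orthogonal Procrustes residual ~ 0)
    pts = rng.normal(size=(15, 2))
    res = pcoa(_euclidean_dm(pts), n_axes=2)
    X = pts - pts.mean(axis=0)
    Y = res.coordinates.to_numpy()
    U, _, Vt = np.linalg.svd(Y.T @ X)
    R = U @ Vt
    assert np.linalg.norm(Y @ R - X) < 1e-8
    assert res.eigenvalues[res.eigenvalues < -1e-8].size == 0


def test_pcoa_agrees_with_skbio(rng):
    skbio = pytest.importorskip("skbio")
    pts = rng.normal(size=(10, 3))
    D = _euclidean_dm(pts)
    ours = pcoa(D, n_axes=2)
    theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D))
    ref = theirs.samples.to_numpy()[:, :2]
    got = ours.coordinates.to_numpy()
    for j in range(2):  # axis signs are arbitrary
        flip = np.sign(got[:, j] @ ref[:, j]) or 1.0
        assert np.allclose(got[:, j] * flip, ref[:, j], atol=1e-6)


def test_pcoa_rejects_asymmetric_input():
    with pytest.raises(ValueError):
        pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))
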