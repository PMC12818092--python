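"""Published reference tallies for the Central European hawthorn complex.

The three parental species — *Crataegus laevigata* (L), *C. monogyna* (M),
*C. rhipidophylla* (R) — and their hybrids *C. × media* (MED, L×M),
*C. × macrocarpa* (MAC, L×R) and *C. × subsphaerica* (SUB, M×R) were surveyed
in ten Austrian and Slovakian populations.  The printed per-taxon tallies of
that survey (clone counts, leaf-ploidy counts and index ranges, and the full
embryo/endosperm pathway matrix) are reproduced here as validation inputs:
the analysis operations are run on them and must recover the published
derived figures (clonality percentages, ploidy frequencies, sexual shares,
pathway notations).
"""

from __future__ import annotations

from .cytometry import AMBIGUOUS, AUTONOMOUS, PSEUDOGAMOUS, SEXUAL
from .genotypes import ClonalAssignment

__all__ = [
    "CLONALITY_COUNTS",
    "LEAF_PLOIDY_COUNTS",
    "LEAF_INDEX_RANGES",
    "PATHWAY_CELLS",
    "expand_clonality_counts",
    "expand_pathway_seeds",
]

# Per-taxon clone bookkeeping: sampled ramets, distinct genets, genets with
# >= 2 members, and ramets belonging to those multi-member genets.
CLONALITY_COUNTS: dict[str, dict[str, int]] = {
    "L":   {"n_ramets": 111, "n_genets": 109, "n_clonal_genets": 1,
            "n_clonal_ramets": 3},
    "M":   {"n_ramets": 32, "n_genets": 32, "n_clonal_genets": 0,
            "n_clonal_ramets": 0},
    "MED": {"n_ramets": 17, "n_genets": 17, "n_clonal_genets": 0,
            "n_clonal_ramets": 0},
    "R":   {"n_ramets": 71, "n_genets": 20, "n_clonal_genets": 11,
            "n_clonal_ramets": 62},
    "MAC": {"n_ramets": 57, "n_genets": 25, "n_clonal_genets": 11,
            "n_clonal_ramets": 43},
    "SUB": {"n_ramets": 18, "n_genets": 11, "n_clonal_genets": 5,
            "n_clonal_ramets": 12},
}

# Leaf ploidy counts among the 306 successfully genotyped individuals.
LEAF_PLOIDY_COUNTS: dict[int, int] = {2: 158, 3: 124, 4: 24}

# Leaf DAPI index ranges (sample G1 peak / Pisum standard peak) per ploidy.
LEAF_INDEX_RANGES: dict[int, tuple[float, float]] = {
    2: (0.175, 0.206),
    3: (0.240, 0.320),
    4: (0.370, 0.407),
}

# The published pathway matrix: every (maternal, embryo, endosperm) ploidy
# combination with its expected mode, per-seed notation and per-taxon seed
# counts.  Combinations printed as aggregated ranges (e.g. ⚇6+♂1–4) are
# expanded; the count is attached to the first combination of the group so
# that taxon totals are preserved.  Two printed cells are internally
# inconsistent with the rule set and carry expected values of None — they
# take part in count arithmetic but not in the notation check.
# Fields: (m, embryo, endosperm, mode, notation, counts)
PATHWAY_CELLS: list[tuple] = [
    # --- diploid mothers -------------------------------------------------
    (2, 2, 3, SEXUAL, "♀1+♂1+(⚇2+♂1)", {"L": 419, "M": 31, "MED": 49, "SUB": 4}),
    (2, 3, 4, SEXUAL, "♀1+♂2+(⚇2+♂2)", {"L": 16, "MED": 2, "SUB": 6}),
    (2, 3, 5, SEXUAL, "♀2+♂1+(⚇4+♂1)", {"L": 1}),
    (2, 4, 5, SEXUAL, "♀1+♂3+(⚇2+♂3)", {"L": 1}),
    (2, 2, 6, PSEUDOGAMOUS, "♀2+(⚇4+♂2)", {"L": 4}),
    (2, 2, 4, AUTONOMOUS, "♀2+(⚇4)", {"L": 3}),
    (2, 3, "≥8", AMBIGUOUS, "3+(≥8)", {"L": 2}),
    (2, 5, "≥10", AMBIGUOUS, "5+(≥10)", {"L": 1, "MED": 1}),
    (2, 2, 10, None, None, {"L": 1}),  # inconsistent cell, excluded from check
    # --- triploid mothers ------------------------------------------------
    (3, 2, 3, SEXUAL, "♀1+♂1+(⚇2+♂1)", {"L": 9, "M": 2}),
    (3, 2.5, 4, SEXUAL, "♀∼1.5+♂1+(⚇∼3+♂1)", {"MAC": 2}),
    (3, 3, 5, SEXUAL, "♀2+♂1+(⚇4+♂1)", {"R": 1, "MAC": 2}),
    (3, 3, 4, SEXUAL, "♀1+♂2+(⚇2+♂2)", {"L": 1, "R": 1}),
    (3, 4, 7, SEXUAL, "♀3+♂1+(⚇6+♂1)", {"R": 5, "MAC": 18, "SUB": 3}),
    (3, 4, 6, SEXUAL, "♀2+♂2+(⚇4+♂2)", {"MAC": 1}),
    (3, 5, 8, SEXUAL, "♀3+♂2+(⚇6+♂2)", {"R": 10, "MAC": 11, "SUB": 3}),
    (3, 6, 9, SEXUAL, "♀3+♂3+(⚇6+♂3)", {}),
    (3, 3, 7, PSEUDOGAMOUS, "♀3+(⚇6+♂1)",
     {"L": 9, "M": 2, "R": 155, "MAC": 105, "SUB": 32}),
    (3, 3, 8, PSEUDOGAMOUS, "♀3+(⚇6+♂2)", {}),
    (3, 3, 9, PSEUDOGAMOUS, "♀3+(⚇6+♂3)", {}),
    (3, 3, 10, PSEUDOGAMOUS, "♀3+(⚇6+♂4)", {}),
    (3, 3, ">10", PSEUDOGAMOUS, "♀3+(>10)", {"R": 11, "SUB": 2, "MAC": 4}),
    (3, 3, 6, AUTONOMOUS, "♀3+(⚇6)", {"MAC": 1, "SUB": 1}),
    (3, 4, 8, AMBIGUOUS, "4+(8)", {"R": 3, "MAC": 5}),
    (3, 4, ">10", AMBIGUOUS, "4+(>10)", {"R": 2}),
    (3, 5, ">10", AMBIGUOUS, "5+(>10)", {}),
    (3, 6, ">10", AMBIGUOUS, "6+(>10)", {}),
    (3, 5, 7, None, None, {"MAC": 1}),  # inconsistent cell, excluded from check
    # --- tetraploid mothers ----------------------------------------------
    (4, 4, 6, SEXUAL, "♀2+♂2+(⚇4+♂2)", {"R": 1, "MAC": 1, "SUB": 3}),
    (4, 6, 10, SEXUAL, "♀4+♂2+(⚇8+♂2)", {"R": 6, "MAC": 7, "SUB": 1}),
    (4, 6, 9, SEXUAL, "♀3+♂3+(⚇6+♂3)", {"MAC": 1}),
    (4, 4, 9, PSEUDOGAMOUS, "♀4+(⚇8+♂1)",
     {"R": 31, "MAC": 15, "SUB": 3}),
    (4, 4, 10, PSEUDOGAMOUS, "♀4+(⚇8+♂2)", {}),
    (4, 4, 11, PSEUDOGAMOUS, "♀4+(⚇8+♂3)", {}),
    (4, 4, 12, PSEUDOGAMOUS, "♀4+(⚇8+♂4)", {}),
    (4, 4, ">12", PSEUDOGAMOUS, "♀4+(>12)", {"R": 2, "MAC": 1, "SUB": 1}),
    (4, 6, "≥12", AMBIGUOUS, "6+(≥12)", {"R": 6, "MAC": 1}),
]


def expand_clonality_counts(
    counts: dict[str, dict[str, int]] | None = None,
) -> tuple[ClonalAssignment, dict[str, str]]:
    """Build a concrete genet assignment realizing the published per-taxon
    counts, so the clonality summarizer can be run on it.

    Multi-member genet sizes are chosen as evenly as possible over the
    published number of clonal genets; only the aggregate quantities the
    summary reports depend on the counts, not on the particular split.
    """
    counts = counts if counts is not None else CLONALITY_COUNTS
    ids: list[str] = []
    genet_ids: list[str] = []
    labels: dict[str, str] = {}
    for taxon, c in counts.items():
        n_singleton = c["n_ramets"] - c["n_clonal_ramets"]
        sizes: list[int] = []
        if c["n_clonal_genets"]:
            base = c["n_clonal_ramets"] // c["n_clonal_genets"]
            rem = c["n_clonal_ramets"] - base * c["n_clonal_genets"]
            sizes = [base + (1 if i < rem else 0)
                     for i in range(c["n_clonal_genets"])]
            assert all(s >= 2 for s in sizes), "counts imply a singleton clone"
        k = 0
        for gi, size in enumerate(sizes):
            genet = f"{taxon}_clone{gi}"
            for _ in range(size):
                ind = f"{taxon}_{k}"
                ids.append(ind)
                genet_ids.append(genet)
                labels[ind] = taxon
                k += 1
        for _ in range(n_singleton):
            ind = f"{taxon}_{k}"
            ids.append(ind)
            genet_ids.append(ind)
            labels[ind] = taxon
            k += 1
        assert len({g for i, g in zip(ids, genet_ids) if labels[i] == taxon}) \
            == c["n_genets"], f"{taxon}: counts are internally inconsistent"
    return ClonalAssignment(ids=ids, genet_ids=genet_ids), labels


def expand_pathway_seeds(taxa: set[str] | None = None):
    """Expand the pathway matrix counts into per-seed records.

    Returns a DataFrame with columns taxon, maternal_ploidy, embryo,
    endosperm — one row per published seed — suitable for
    :func:`crataegus.cytometry.summarize_reproduction`.
    """
    import pandas as pd

    rows = []
    for m, e, n, _mode, _notation, cell_counts in PATHWAY_CELLS:
        for taxon, count in cell_counts.items():
            if taxa is not None and taxon not in taxa:
                continue
            rows.extend(
                {"taxon": taxon, "maternal_ploidy": m, "embryo": e,
                 "endosperm": n}
                for _ in range(count)
            )
    return pd.DataFrame(rows)
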