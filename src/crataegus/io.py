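"""Readers and writers for the study's plain-text file formats.

* genotype CSV — one row per individual: ``individual_id, population_id,
  taxon_label, ploidy`` then one column per locus holding '/'-separated
  allele sizes in bp (empty = missing locus);
* locus metadata CSV — ``name, motif_length[, size_min, size_max]``;
* Q-matrix CSV — ``individual_id`` + one column per cluster;
* cluster map CSV — ``cluster, species, subgroup``;
* FCM CSV — ``sample_id, taxon, tissue, standard, index``;
* seed CSV — ``seed_id, mother_id, taxon, maternal_ploidy, embryo_index,
  endosperm_index`` (or pre-assigned ``embryo``/``endosperm`` ploidies);
* TPS landmark files — the standard geometric-morphometrics dialect
  (``LM=13`` header, coordinate lines, ``ID=`` key; ``IMAGE=``/``SCALE=``
  lines are ignored).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import DistanceMatrix, Genotype, Locus

__all__ = [
    "read_locus_csv",
    "write_locus_csv",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_distance_csv",
    "write_distance_csv",
    "read_qmatrix_csv",
    "read_cluster_map_csv",
    "read_tps",
    "write_tps",
]

_META_COLS = ["individual_id", "population_id", "taxon_label", "ploidy"]


def read_locus_csv(path) -> dict[str, Locus]:
    df = pd.read_csv(path, dtype={"name": str})
    loci = {}
    for _, r in df.iterrows():
        window = (
            (int(r["size_min"]), int(r["size_max"]))
            if "size_min" in df.columns and not pd.isna(r.get("size_min"))
            else (100, 500)
        )
        loci[r["name"]] = Locus(r["name"], int(r["motif_length"]), window)
    return loci


def write_locus_csv(loci: dict[str, Locus], path) -> None:
    rows = [
        {"name": l.name, "motif_length": l.motif_length,
         "size_min": l.size_window[0], "size_max": l.size_window[1]}
        for l in loci.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_genotype_csv(path, loci: dict[str, Locus],
                      enforce_window: bool = True) -> list[Genotype]:
    """Read genotypes; alleles outside a locus' size window are dropped with
    a warning (fragments outside the scoring window are unreliable)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    locus_cols = [c for c in df.columns if c not in _META_COLS]
    unknown = [c for c in locus_cols if c not in loci]
    if unknown:
        raise ValueError(f"{path}: loci without metadata: {unknown}")
    out = []
    for _, r in df.iterrows():
        alleles: dict[str, tuple[int, ...]] = {}
        for c in locus_cols:
            cell = r[c]
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            sizes = [int(float(s)) for s in str(cell).split("/")]
            if enforce_window:
                lo, hi = loci[c].size_window
                kept = [s for s in sizes if lo <= s <= hi]
                if len(kept) < len(sizes):
                    dropped = sorted(set(sizes) - set(kept))
                    warnings.warn(
                        f"{r['individual_id']}/{c}: alleles {dropped} outside "
                        f"size window [{lo}, {hi}] dropped",
                        stacklevel=2,
                    )
                sizes = kept
            if sizes:
                alleles[c] = tuple(sorted(sizes))
        taxon = r["taxon_label"] if not pd.isna(r["taxon_label"]) else None
        out.append(
            Genotype(
                individual_id=r["individual_id"],
                population_id=r["population_id"],
                ploidy=int(r["ploidy"]),
                alleles=alleles,
                taxon_label=taxon,
            )
        )
    return out


def write_genotype_csv(genotypes: Sequence[Genotype], path) -> None:
    locus_names = sorted({l for g in genotypes for l in g.alleles})
    rows = []
    for g in genotypes:
        row = {
            "individual_id": g.individual_id,
            "population_id": g.population_id,
            "taxon_label": g.taxon_label or "",
            "ploidy": g.ploidy,
        }
        for l in locus_names:
            row[l] = "/".join(str(s) for s in g.alleles[l]) if l in g.alleles else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_distance_csv(dist: DistanceMatrix, path) -> None:
    dist.to_dataframe().to_csv(path)


def read_distance_csv(path, metric: str = "unknown") -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(ids=list(df.index.astype(str)),
                          values=df.to_numpy(dtype=float), metric=metric)


def read_qmatrix_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path).set_index("individual_id")
    return df.astype(float)


def read_cluster_map_csv(path):
    from .admixture import ClusterSpeciesMap

    df = pd.read_csv(path, dtype=str)
    clusters = {r["cluster"]: (r["species"], r["subgroup"]) for _, r in df.iterrows()}
    species = sorted({s for s, _ in clusters.values()})
    # hybrid naming defaults to the hawthorn table where applicable
    default = ClusterSpeciesMap.default_crataegus().hybrid_names
    hybrids = {}
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            key = frozenset({a, b})
            hybrids[key] = default.get(key, f"{a}x{b}")
    return ClusterSpeciesMap(clusters=clusters, hybrid_names=hybrids)


# ---------------------------------------------------------------------------
# TPS landmark files


def read_tps(path, expect_landmarks: int | None = 13) -> list[dict]:
    """Parse a TPS landmark file into ``[{"id": ..., "coords": (k, 2)}]``.

    Raises a ``ValueError`` naming the specimen when a record's landmark
    count differs from ``expect_landmarks``.
    """
    records: list[dict] = []
    lm_count = None
    coords: list[list[float]] = []
    spec_id = None

    def flush(line_no):
        nonlocal lm_count, coords, spec_id
        if lm_count is None:
            return
        if len(coords) != lm_count:
            raise ValueError(
                f"{path}:{line_no}: specimen {spec_id or '?'} declares "
                f"LM={lm_count} but has {len(coords)} coordinate lines"
            )
        if expect_landmarks is not None and lm_count != expect_landmarks:
            raise ValueError(
                f"{path}: specimen {spec_id or '?'} has {lm_count} landmarks, "
                f"expected {expect_landmarks}"
            )
        records.append(
            {"id": spec_id or f"specimen_{len(records)}",
             "coords": np.asarray(coords, dtype=float)}
        )
        lm_count, coords, spec_id = None, [], None

    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                flush(line_no)
                lm_count = int(line.split("=", 1)[1])
            elif upper.startswith("ID="):
                spec_id = line.split("=", 1)[1].strip()
            elif upper.startswith(("IMAGE=", "SCALE=", "COMMENT=")):
                continue
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{line_no}: malformed coordinate line")
                coords.append([float(parts[0]), float(parts[1])])
    flush("eof")
    return records


def write_tps(records: Sequence[dict], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            coords = np.asarray(rec["coords"], dtype=float)
            fh.write(f"LM={coords.shape[0]}\n")
            for x, y in coords:
                fh.write(f"{x:.6f} {y:.6f}\n")
            fh.write(f"ID={rec['id']}\n")
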