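"""Flow-cytometry ploidy binning and seed-screen reproductive-mode inference.

Flow cytometry reports, per sample, the ratio ("index") of the G1 fluorescence
peak of the sample to that of an internal standard (*Pisum sativum* or *Carex
acutiformis*).  Indices cluster by ploidy; a 1-D Gaussian mixture fitted per
(tissue, standard) context yields ploidy bins defined as mean ± 2 sd, with
the lowest bin assigned the base ploidy (diploid for leaves and embryos).

The flow cytometric seed screen (FCSS) measures embryo and endosperm ploidy
of single seeds.  Endosperm arises from the fusion of the central cell (two
polar nuclei, ⚇ = 2 × egg) with zero or more sperm, the embryo from the egg
(♀) with zero or one sperm (♂).  Comparing maternal (m), embryo (e) and
endosperm (n) ploidies therefore identifies the reproductive pathway:

* **sexual**      e = ♀ + ♂,   n = 2♀ + ♂  (same sperm ploidy in both);
* **autonomous apomixis**    e = m, n = 2m (no paternal contribution);
* **pseudogamous apomixis**  e = m, n = 2m + ♂n with 1 ≤ ♂n ≤ ``smax``
  (maternal embryo, fertilized endosperm — the common mode in apomictic
  Rosaceae);
* endosperm far above 2m + ``smax`` in polyploid mothers is recorded as
  pseudogamous with sperm contribution "> smax" and flagged (polyspermy or
  endoreduplication);
* anything else is **ambiguous** and reported as "e+(n)".
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .util import round_half_up

__all__ = [
    "PloidyComponent",
    "PloidyBinning",
    "ReproductivePathway",
    "fit_ploidy_bins",
    "assign_ploidy",
    "infer_pathway",
    "summarize_reproduction",
]

SEXUAL = "sexual"
PSEUDOGAMOUS = "apomictic-pseudogamous"
AUTONOMOUS = "apomictic-autonomous"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class PloidyComponent:
    mean: float
    sd: float
    low: float   # mean - 2 sd
    high: float  # mean + 2 sd
    ploidy: int
    label: str   # e.g. "2x"


@dataclass
class PloidyBinning:
    """Fitted ploidy bins for one (tissue, standard) context."""

    components: tuple[PloidyComponent, ...]
    base_ploidy: int = 2
    context: tuple[str, str] | None = None
    accepted: bool = True
    bic: float | None = None
    n_samples: int = 0

    @classmethod
    def from_ranges(
        cls,
        ranges: dict[int, tuple[float, float]],
        base_ploidy: int = 2,
        context: tuple[str, str] | None = None,
    ) -> "PloidyBinning":
        """Build a binning directly from published index ranges (each range
        interpreted as mean ± 2 sd)."""
        comps = []
        for ploidy in sorted(ranges):
            lo, hi = ranges[ploidy]
            mean, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
            comps.append(PloidyComponent(mean, sd, lo, hi, ploidy, f"{ploidy}x"))
        return cls(components=tuple(comps), base_ploidy=base_ploidy, context=context)


def fit_ploidy_bins(
    records: Iterable[float],
    base_ploidy: int = 2,
    max_components: int = 6,
    context: tuple[str, str] | None = None,
    random_state: int = 0,
) -> PloidyBinning:
    """Fit ploidy bins to fluorescence indices of one context.

    A 1-D Gaussian mixture is fitted by EM for 1..``max_components``
    components; the component count is chosen by BIC (ties toward fewer).
    Components are sorted by mean; each bin spans mean ± 2 sd.  The lowest
    component is labelled ``base_ploidy`` and the others
    ``round(base_ploidy * mean_i / mean_lowest)``; a label collision means
    the peaks cannot be told apart and the fit is rejected.
    """
    x = np.asarray(list(records), dtype=float)
    if np.any(x <= 0):
        raise ValueError("fluorescence indices must be positive")
    cap = min(max_components, len(x) // 5)
    if cap < 1:
        raise ValueError(
            f"{len(x)} records cannot support any mixture component "
            "(need at least 5 per component)"
        )
    if len(x) < 30:
        warnings.warn("fewer than 30 records; bin estimates may be unstable",
                      stacklevel=2)
    X = x.reshape(-1, 1)
    best_k, best_bic, best_gm = None, np.inf, None
    for k in range(1, cap + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=3,
            random_state=random_state,
            reg_covar=1e-10,
        ).fit(X)
        bic = gm.bic(X)
        if bic < best_bic - 1e-9:  # strict improvement: ties keep fewer
            best_k, best_bic, best_gm = k, bic, gm
    assert best_gm is not None
    means = best_gm.means_.ravel()
    sds = np.sqrt(best_gm.covariances_.reshape(-1))
    order = np.argsort(means)
    means, sds = means[order], sds[order]

    ploidies = [base_ploidy] + [
        int(round(base_ploidy * m / means[0])) for m in means[1:]
    ]
    if len(set(ploidies)) != len(ploidies):
        raise ValueError(
            "ploidy bins unresolvable: component means imply duplicate labels "
            f"{ploidies}"
        )
    comps = tuple(
        PloidyComponent(float(m), float(s), float(m - 2 * s), float(m + 2 * s),
                        p, f"{p}x")
        for m, s, p in zip(means, sds, ploidies)
    )
    accepted = all(
        comps[i].high < comps[i + 1].low for i in range(len(comps) - 1)
    )
    if not accepted:
        warnings.warn("adjacent ploidy ranges overlap; strict assignment disabled",
                      stacklevel=2)
    return PloidyBinning(
        components=comps,
        base_ploidy=base_ploidy,
        context=context,
        accepted=accepted,
        bic=float(best_bic),
        n_samples=len(x),
    )


def assign_ploidy(index: float, binning: PloidyBinning, mode: str = "strict") -> str:
    """Assign a ploidy label to one fluorescence index.

    ``strict``: the label of the unique mean ± 2 sd range containing the
    index; "intermediate" between ranges; "out-of-range" below the lowest or
    above the highest range.  ``nearest``: label of the nearest component
    mean, demoted to a half-integer label (e.g. "2.5x") when the nearest
    integer bin is more than 2 sd away — endosperm and imbalanced-gamete
    tissues routinely produce such intermediate values.
    """
    if index <= 0:
        raise ValueError("index must be positive")
    comps = binning.components
    if mode == "strict":
        if not binning.accepted:
            raise ValueError("binning was rejected (overlapping ranges); "
                             "use mode='nearest'")
        for c in comps:
            if c.low <= index <= c.high:
                return c.label
        if index < comps[0].low or index > comps[-1].high:
            return "out-of-range"
        return "intermediate"
    if mode == "nearest":
        c = min(comps, key=lambda c: abs(index - c.mean))
        if abs(index - c.mean) <= 2 * c.sd:
            return c.label
        frac = binning.base_ploidy * index / comps[0].mean
        half = round(frac * 2) / 2.0
        return f"{half:g}x"
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# pathway inference


@dataclass
class ReproductivePathway:
    """Inferred gametic contributions behind one seed.

    ``egg`` (♀) and ``central_cell`` (⚇ = 2♀) are in ploidy units (×);
    ``sperm_embryo`` (♂e) is 0 for unfertilized (apomictic) embryos;
    ``sperm_endosperm`` (♂n) may be a string bound like "> 4" for extreme
    endosperm values.
    """

    maternal: int
    embryo: str
    endosperm: str
    mode: str
    notation: str
    egg: float | None = None
    sperm_embryo: int | None = None
    central_cell: float | None = None
    sperm_endosperm: float | str | None = None
    flagged: bool = False
    note: str = ""


_BOUND_RE = re.compile(r"^\s*(>=|≥|>)\s*([0-9.]+)\s*$")


def _parse_ploidy(value) -> tuple[float, str, bool]:
    """Return (numeric value for rule checks, display text, open-bound flag).

    Open lower bounds: ">x" is evaluated at x + 1, "≥x" at x; both are
    flagged and keep their original text in ambiguous notations.
    """
    if isinstance(value, str):
        m = _BOUND_RE.match(value)
        if m:
            op, num = m.groups()
            num = float(num)
            if op == ">":
                return num + 1.0, f">{num:g}", True
            return num, f"≥{num:g}", True
        value = float(value)
    v = float(value)
    return v, f"{v:g}", False


def _fmt_egg(f: float) -> str:
    return f"{f:g}" if float(f).is_integer() else f"∼{f:g}"


def infer_pathway(
    m: int,
    e,
    n,
    tol: float = 0.25,
    smax: int = 4,
    extended_min_maternal: int = 3,
    unbalanced_egg_max_sperm: int | None = None,
) -> ReproductivePathway:
    """Infer the reproductive pathway of one seed from (maternal, embryo,
    endosperm) ploidies.

    Rules are checked in order and the first match wins (they are mutually
    exclusive for integer inputs at ``tol`` < 0.5):

    1. sexual — ♀ = n − e and ♂ = 2e − n give a half-integer egg in
       [0.5, m] and an integer sperm in {1, 2, 3}, each within ``tol``;
       the same sperm fertilizes egg and central cell (n = 2♀ + ♂);
    2. autonomous apomixis — e = m and n = 2m;
    3. pseudogamous apomixis — e = m and 2m + 1 ≤ n ≤ 2m + ``smax``;
    4. extended apomixis (maternal ploidy ≥ ``extended_min_maternal``
       only) — e = m and n beyond 2m + ``smax``: pseudogamous with the
       endosperm sperm contribution recorded as "> smax" and flagged;
    5. otherwise ambiguous, notated "e+(n)".

    ``unbalanced_egg_max_sperm`` optionally caps the sperm ploidy accepted in
    the sexual rule when the egg is neither reduced (m/2) nor unreduced (m),
    declaring such seeds ambiguous instead.
    """
    if m not in (2, 3, 4):
        raise ValueError(f"maternal ploidy must be 2, 3 or 4, got {m}")
    if tol < 0 or tol >= 0.5:
        raise ValueError("tol must lie in [0, 0.5)")
    e_v, e_txt, e_open = _parse_ploidy(e)
    n_v, n_txt, n_open = _parse_ploidy(n)
    if e_v <= 0 or n_v <= 0:
        raise ValueError("embryo and endosperm ploidies must be positive")
    flagged_bound = e_open or n_open
    note = "open ploidy bound evaluated at its limit" if flagged_bound else ""

    # (1) sexual
    f_raw = n_v - e_v
    me_raw = 2.0 * e_v - n_v
    f = round(f_raw * 2.0) / 2.0
    me = int(round(me_raw))
    sexual_ok = (
        abs(f_raw - f) <= tol
        and abs(me_raw - me) <= tol
        and 0.5 <= f <= m
        and 1 <= me <= 3
    )
    if sexual_ok and unbalanced_egg_max_sperm is not None:
        balanced = abs(2 * f - m) < 1e-9 or abs(f - m) < 1e-9  # reduced or unreduced
        if not balanced and me > unbalanced_egg_max_sperm:
            sexual_ok = False
    if sexual_ok:
        cc = 2.0 * f
        egg_s, cc_s = _fmt_egg(f), _fmt_egg(cc) if not float(f).is_integer() else f"{cc:g}"
        if not float(f).is_integer():
            cc_s = f"∼{cc:g}"
        notation = f"♀{egg_s}+♂{me}+(⚇{cc_s}+♂{me})"
        return ReproductivePathway(
            m, e_txt, n_txt, SEXUAL, notation,
            egg=f, sperm_embryo=me, central_cell=cc, sperm_endosperm=me,
            flagged=flagged_bound, note=note,
        )

    maternal_embryo = abs(e_v - m) <= tol

    # (2) autonomous apomixis
    if maternal_embryo and abs(n_v - 2 * m) <= tol:
        return ReproductivePathway(
            m, e_txt, n_txt, AUTONOMOUS, f"♀{m}+(⚇{2 * m})",
            egg=float(m), sperm_embryo=0, central_cell=float(2 * m),
            sperm_endosperm=0, flagged=flagged_bound, note=note,
        )

    # (3) pseudogamous apomixis
    if maternal_embryo and (2 * m + 1 - tol) <= n_v <= (2 * m + smax + tol):
        sn = int(round(n_v - 2 * m))
        sn = min(max(sn, 1), smax)
        return ReproductivePathway(
            m, e_txt, n_txt, PSEUDOGAMOUS, f"♀{m}+(⚇{2 * m}+♂{sn})",
            egg=float(m), sperm_embryo=0, central_cell=float(2 * m),
            sperm_endosperm=sn, flagged=flagged_bound, note=note,
        )

    # (4) extended apomixis: endosperm beyond 2m + smax in polyploid mothers
    if (
        maternal_embryo
        and m >= extended_min_maternal
        and n_v > 2 * m + smax + tol
    ):
        return ReproductivePathway(
            m, e_txt, n_txt, PSEUDOGAMOUS, f"♀{m}+(>{2 * m + smax})",
            egg=float(m), sperm_embryo=0, central_cell=float(2 * m),
            sperm_endosperm=f"> {smax}", flagged=True,
            note=(note + "; " if note else "")
            + "endosperm exceeds 2m + smax (polyspermy or endoreduplication)",
        )

    # (5) ambiguous
    return ReproductivePathway(
        m, e_txt, n_txt, AMBIGUOUS, f"{e_txt}+({n_txt})",
        flagged=flagged_bound, note=note,
    )


def summarize_reproduction(
    seeds: pd.DataFrame,
    taxa: Sequence[str] | None = None,
    tol: float = 0.25,
    smax: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-taxon reproductive-mode summary.

    ``seeds`` needs columns ``taxon``, ``maternal_ploidy``, ``embryo``,
    ``endosperm`` (ploidies; embryo/endosperm may carry open bounds like
    ">10").  Returns ``(detail, aggregate)``:

    * ``detail`` — one row per (taxon, maternal ploidy, pathway notation)
      with mode, seed count and percentage of the taxon's classified seeds;
    * ``aggregate`` — per taxon: seed total, maternal-ploidy marginals, and
      sexual / apomictic / ambiguous shares.

    Percentages are rounded half-up to one decimal.
    """
    required = {"taxon", "maternal_ploidy", "embryo", "endosperm"}
    if not required.issubset(seeds.columns):
        raise ValueError(f"seeds table needs columns {sorted(required)}")
    if taxa is not None:
        empty = set(taxa) - set(seeds["taxon"].unique())
        if empty:
            warnings.warn(f"no seeds for taxa {sorted(empty)}; omitted", stacklevel=2)

    records = []
    for _, row in seeds.iterrows():
        pw = infer_pathway(int(row["maternal_ploidy"]), row["embryo"],
                           row["endosperm"], tol=tol, smax=smax)
        records.append(
            {
                "taxon": row["taxon"],
                "maternal_ploidy": int(row["maternal_ploidy"]),
                "notation": pw.notation,
                "mode": pw.mode,
            }
        )
    classified = pd.DataFrame(records)

    detail_rows = []
    agg_rows = []
    for taxon, grp in classified.groupby("taxon", sort=True):
        total = len(grp)
        counts = (
            grp.groupby(["maternal_ploidy", "notation", "mode"])
            .size()
            .reset_index(name="count")
            .sort_values(["maternal_ploidy", "count"], ascending=[True, False])
        )
        for _, r in counts.iterrows():
            detail_rows.append(
                {
                    "taxon": taxon,
                    "maternal_ploidy": r["maternal_ploidy"],
                    "notation": r["notation"],
                    "mode": r["mode"],
                    "count": int(r["count"]),
                    "pct": round_half_up(100.0 * r["count"] / total, 1),
                }
            )
        mode_counts = grp["mode"].value_counts()
        sexual = int(mode_counts.get(SEXUAL, 0))
        apo = int(mode_counts.get(PSEUDOGAMOUS, 0) + mode_counts.get(AUTONOMOUS, 0))
        amb = int(mode_counts.get(AMBIGUOUS, 0))
        rec = {
            "taxon": taxon,
            "n_seeds": total,
            "sexual_pct": round_half_up(100.0 * sexual / total, 1),
            "apomictic_pct": round_half_up(100.0 * apo / total, 1),
            "ambiguous_pct": round_half_up(100.0 * amb / total, 1),
        }
        for p, c in grp["maternal_ploidy"].value_counts().sort_index().items():
            rec[f"maternal_{p}x_pct"] = round_half_up(100.0 * c / total, 1)
        agg_rows.append(rec)

    detail = pd.DataFrame(detail_rows)
    aggregate = pd.DataFrame(agg_rows).set_index("taxon")
    return detail, aggregate
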