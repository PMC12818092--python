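"""Landmark and trait morphometrics: GPA, relative warps, CDA, LOO-LDA.

Leaf shape is captured as 13 two-dimensional landmarks per leaf, digitized
separately for leaves of flowering shoots and of short vegetative shoots.
The analysis chain is:

generalized Procrustes alignment -> robust within-individual outlier removal
(median + 2 MAD on Procrustes distances) -> per-individual averaging and
concatenation into a 26-landmark composite -> thin-plate-spline imputation of
missing landmark blocks -> relative warps (shape PCA) and, together with
fruit traits, canonical discriminant analysis with hybrids projected as
passive samples, validated by leave-one-out linear discriminant analysis.

Shapes are ``(k, 2)`` arrays; collections are ``(n, k, 2)``.  Reflection is
forbidden in the optimal rotation by default because leaves have a fixed
left/right landmark chirality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .util import round_half_up

__all__ = [
    "AlignedShapes",
    "DiscriminantModel",
    "RelativeWarpResult",
    "PCAResult",
    "LooLdaResult",
    "centroid_size",
    "procrustes_distance",
    "gpa_align",
    "filter_outlier_shapes",
    "average_and_combine",
    "impute_missing_landmarks",
    "relative_warps",
    "prune_correlated",
    "cda_with_passive",
    "loo_lda",
    "chained_impute",
    "pca_traits",
]


def centroid_size(shape: np.ndarray) -> float:
    s = np.asarray(shape, dtype=float)
    return float(np.sqrt(((s - s.mean(axis=0)) ** 2).sum()))


def _optimal_rotation(target: np.ndarray, moving: np.ndarray,
                      allow_reflection: bool = False) -> np.ndarray:
    """Rotation R minimizing ||target - moving @ R||_F (both centered)."""
    H = moving.T @ target
    U, _, Vt = np.linalg.svd(H)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return R


def _normalize(shape: np.ndarray) -> np.ndarray:
    s = np.asarray(shape, dtype=float)
    s = s - s.mean(axis=0)
    size = np.sqrt((s ** 2).sum())
    if size == 0:
        raise ValueError("degenerate shape with zero centroid size")
    return s / size


def procrustes_distance(a: np.ndarray, b: np.ndarray,
                        allow_reflection: bool = False) -> float:
    """Partial Procrustes distance between two configurations (translation,
    scale and rotation removed)."""
    an, bn = _normalize(a), _normalize(b)
    R = _optimal_rotation(an, bn, allow_reflection)
    return float(np.linalg.norm(an - bn @ R))


@dataclass
class AlignedShapes:
    aligned: np.ndarray          # (n, k, 2), centered, unit centroid size
    mean_shape: np.ndarray       # (k, 2), unit centroid size
    centroid_sizes: np.ndarray   # (n,), original sizes
    iterations: int
    converged: bool


def gpa_align(shapes: np.ndarray, allow_reflection: bool = False,
              tol: float = 1e-8, max_iter: int = 100) -> AlignedShapes:
    """Generalized Procrustes alignment.

    Each configuration is translated to the origin and scaled to unit
    centroid size, then iteratively rotated to the current mean shape; the
    mean is recomputed (and renormalized) until it moves by less than
    ``tol`` or ``max_iter`` iterations pass.
    """
    arr = np.asarray(shapes, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError("shapes must be an (n, k, 2) array")
    if arr.shape[0] < 2:
        raise ValueError("need at least two shapes")
    sizes = np.array([centroid_size(s) for s in arr])
    if np.any(sizes == 0):
        raise ValueError("degenerate shape with zero centroid size")
    norm = np.stack([_normalize(s) for s in arr])
    mean = norm[0].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rotated = np.stack(
            [s @ _optimal_rotation(mean, s, allow_reflection) for s in norm]
        )
        new_mean = _normalize(rotated.mean(axis=0))
        # align the new mean back onto the old one so the frame is stable
        new_mean = new_mean @ _optimal_rotation(mean, new_mean, allow_reflection)
        shift = float(np.linalg.norm(new_mean - mean))
        mean = new_mean
        norm = rotated
        if shift < tol:
            converged = True
            break
    return AlignedShapes(aligned=norm, mean_shape=mean, centroid_sizes=sizes,
                         iterations=it, converged=converged)


def filter_outlier_shapes(
    aligned: np.ndarray, individual_ids: Sequence[str]
) -> tuple[np.ndarray, list[dict]]:
    """Robust within-individual outlier removal.

    Per individual, the Procrustes distance of every leaf to the individual's
    mean shape is computed; leaves strictly exceeding
    ``median + 2 * MAD`` are removed.  Individuals with a single leaf are
    always retained, and at least one leaf survives per individual.
    """
    arr = np.asarray(aligned, dtype=float)
    ids = np.asarray(individual_ids)
    keep = np.ones(len(arr), dtype=bool)
    removals: list[dict] = []
    for ind in np.unique(ids):
        idx = np.where(ids == ind)[0]
        if len(idx) < 2:
            continue
        mean = arr[idx].mean(axis=0)
        d = np.array([procrustes_distance(mean, arr[i]) for i in idx])
        med = float(np.median(d))
        mad = float(np.median(np.abs(d - med)))
        thr = med + 2.0 * mad
        out = d > thr
        if out.all():  # never drop every leaf of an individual
            out[np.argmin(d)] = False
        for i, o, di in zip(idx, out, d):
            if o:
                keep[i] = False
                removals.append(
                    {"index": int(i), "individual_id": str(ind),
                     "distance": float(di), "threshold": thr}
                )
    return keep, removals


def average_and_combine(
    flowering: Mapping[str, np.ndarray],
    short: Mapping[str, np.ndarray],
) -> tuple[list[str], np.ndarray]:
    """Per-individual composite of 26 landmarks (13 flowering + 13 short).

    Inputs map individual id -> ``(m, 13, 2)`` stack of that individual's
    retained aligned leaves per shoot type.  Each block is the coordinate-wise
    mean of its leaves; an absent block yields 13 NaN landmarks to be imputed
    downstream.  Individuals with no leaves in either block are excluded
    with a warning.
    """
    individuals = sorted(set(flowering) | set(short))
    ids, rows = [], []
    for ind in individuals:
        fl = flowering.get(ind)
        sh = short.get(ind)
        if (fl is None or len(fl) == 0) and (sh is None or len(sh) == 0):
            warnings.warn(f"individual {ind} has no leaves; excluded", stacklevel=2)
            continue
        fl_mean = np.asarray(fl, float).mean(axis=0) if fl is not None and len(fl) \
            else np.full((13, 2), np.nan)
        sh_mean = np.asarray(sh, float).mean(axis=0) if sh is not None and len(sh) \
            else np.full((13, 2), np.nan)
        ids.append(ind)
        rows.append(np.vstack([fl_mean, sh_mean]))
    return ids, np.stack(rows) if rows else np.empty((0, 26, 2))


def impute_missing_landmarks(
    composites: np.ndarray, min_observed: int = 3
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Thin-plate-spline imputation of missing landmarks.

    The reference configuration is the mean of all complete composites.  For
    each incomplete specimen a TPS map is fitted from the reference's
    observed-landmark positions to the specimen's observed landmarks; each
    missing landmark is set to the TPS image of the reference's corresponding
    point.  Specimens retaining fewer than ``min_observed`` landmarks are
    excluded (mask False).

    Returns ``(filled, kept_mask, log)``.
    """
    arr = np.asarray(composites, dtype=float).copy()
    missing = np.isnan(arr).any(axis=2)  # (n, k)
    complete = ~missing.any(axis=1)
    if not complete.any():
        raise ValueError("no complete composites to build a reference from")
    reference = arr[complete].mean(axis=0)
    kept = np.ones(len(arr), dtype=bool)
    log: list[dict] = []
    for i in range(len(arr)):
        if not missing[i].any():
            continue
        obs = ~missing[i]
        if obs.sum() < min_observed:
            kept[i] = False
            log.append({"index": i, "action": "excluded",
                        "n_observed": int(obs.sum())})
            continue
        tps = RBFInterpolator(reference[obs], arr[i][obs],
                              kernel="thin_plate_spline")
        arr[i][missing[i]] = tps(reference[missing[i]])
        log.append({"index": i, "action": "imputed",
                    "landmarks": np.where(missing[i])[0].tolist()})
    return arr, kept, log


@dataclass
class RelativeWarpResult:
    scores: np.ndarray        # (n, c)
    pct_variance: np.ndarray  # sums to 100
    components: np.ndarray    # (c, 2k) eigenvectors in the analysis metric
    alpha: float


def _bending_energy_matrix(mean_shape: np.ndarray) -> np.ndarray:
    """Bending-energy matrix of a 2-D reference configuration."""
    k = mean_shape.shape[0]
    d = np.linalg.norm(mean_shape[:, None, :] - mean_shape[None, :, :], axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d > 0, d ** 2 * np.log(d ** 2), 0.0)
    P = np.hstack([np.ones((k, 1)), mean_shape])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    Linv = np.linalg.inv(L)
    Be = Linv[:k, :k]
    return (Be + Be.T) / 2.0


def relative_warps(aligned: np.ndarray, alpha: float = 0.0) -> RelativeWarpResult:
    """Relative warps of Procrustes-aligned configurations.

    ``alpha = 0`` (default) is a plain principal-component analysis of the
    aligned coordinates.  Nonzero ``alpha`` weights the non-affine shape
    subspace by the bending-energy eigenvalues raised to ``-alpha/2``
    (positive alpha emphasizes large-scale deformation), leaving the affine
    component unweighted; the PCA then runs in that weighted metric.
    """
    arr = np.asarray(aligned, dtype=float)
    n, k, _ = arr.shape
    if n < 3:
        raise ValueError("need at least three specimens")
    X = arr.reshape(n, 2 * k)
    Xc = X - X.mean(axis=0)
    if alpha != 0.0:
        mean_shape = arr.mean(axis=0)
        Be = _bending_energy_matrix(mean_shape)
        lam, vec = np.linalg.eigh(Be)
        tolz = 1e-10 * max(lam.max(), 1.0)
        weights = np.where(lam > tolz, np.abs(lam) ** (-alpha / 2.0), 1.0)
        # basis in 2k space: each warp acts identically on x and y
        W = np.kron(vec, np.eye(2))          # (2k, 2k)
        wdiag = np.repeat(weights, 2)
        Xc = (Xc @ W) * wdiag                # projections, warp-weighted
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2
    keep = var > 1e-12 * max(var.max(), 1.0)
    scores = (U * S)[:, keep]
    pct = 100.0 * var[keep] / var[keep].sum()
    return RelativeWarpResult(scores=scores, pct_variance=pct,
                              components=Vt[keep], alpha=alpha)


def prune_correlated(
    traits: pd.DataFrame, r_max: float = 0.9
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop one trait of every pair with Spearman |r| strictly above ``r_max``.

    Pairs are processed in decreasing |r|; in each the lower-variance trait
    is removed and correlations are re-evaluated.  Constant traits are
    dropped up front with a warning.  A pair at exactly ``r_max`` is kept.
    """
    df = traits.copy()
    if df.shape[1] < 2:
        raise ValueError("need at least two traits")
    removed: list[dict] = []
    constant = [c for c in df.columns if df[c].nunique(dropna=True) <= 1]
    for c in constant:
        warnings.warn(f"constant trait {c!r} dropped before correlation",
                      stacklevel=2)
        removed.append({"dropped": c, "kept": None, "r": np.nan,
                        "reason": "constant"})
        df = df.drop(columns=c)
    while df.shape[1] >= 2:
        corr = df.corr(method="spearman").abs()
        np.fill_diagonal(corr.values, 0.0)
        r = float(np.nanmax(corr.values))
        if not (r > r_max):
            break
        i, j = np.unravel_index(np.nanargmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        drop = a if df[a].var() < df[b].var() else b
        keep_col = b if drop == a else a
        removed.append({"dropped": drop, "kept": keep_col, "r": r,
                        "reason": "correlated"})
        df = df.drop(columns=drop)
    return df, removed


@dataclass
class DiscriminantModel:
    """Canonical discriminant axes with optional passively projected samples."""

    coefficients: np.ndarray      # (p, a) canonical coefficient vectors
    eigenvalues: np.ndarray       # (a,)
    active_scores: pd.DataFrame
    passive_scores: pd.DataFrame | None
    group_means: pd.DataFrame     # group centroids in canonical space
    grand_mean: np.ndarray
    groups: list[str]
    pct_discrimination: np.ndarray = field(default=None)


def cda_with_passive(
    traits: pd.DataFrame,
    groups: Sequence[str],
    passive: pd.DataFrame | None = None,
    ridge: float | None = None,
) -> DiscriminantModel:
    """Canonical discriminant analysis with passive projection.

    Canonical axes maximize between-group relative to pooled within-group
    variance (generalized eigenproblem).  ``passive`` samples (hybrids) are
    centered with the *active* grand mean and projected with the same
    coefficients, so they never influence the axes.  A singular within-group
    covariance raises unless ``ridge`` adds a logged diagonal eps.
    """
    X = np.asarray(traits, dtype=float)
    g = np.asarray(groups)
    classes = sorted(set(g))
    if len(classes) < 2:
        raise ValueError("need at least two active groups")
    n, p = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for c in classes:
        Xi = X[g == c]
        mi = Xi.mean(axis=0)
        W += (Xi - mi).T @ (Xi - mi)
        B += len(Xi) * np.outer(mi - grand, mi - grand)
    Wp = W / (n - len(classes))
    eigmin = float(np.linalg.eigvalsh(Wp).min())
    if eigmin < 1e-10 * max(1.0, float(np.abs(Wp).max())):
        if ridge is None:
            raise np.linalg.LinAlgError(
                "within-group covariance is singular; prune traits or pass ridge="
            )
        warnings.warn(f"adding ridge {ridge} to within-group covariance",
                      stacklevel=2)
        Wp = Wp + ridge * np.eye(p)
    from scipy.linalg import eigh as generalized_eigh

    eigvals, eigvecs = generalized_eigh(B, Wp)
    order = np.argsort(eigvals)[::-1]
    a = min(len(classes) - 1, p)
    eigvals = eigvals[order][:a]
    V = eigvecs[:, order][:, :a]
    # scale to unit pooled within-group variance, deterministic sign
    for j in range(a):
        v = V[:, j]
        v = v / np.sqrt(v @ Wp @ v)
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        V[:, j] = v
    cols = [f"Can{j + 1}" for j in range(a)]
    active_scores = pd.DataFrame((X - grand) @ V, index=traits.index, columns=cols)
    passive_scores = None
    if passive is not None:
        if list(passive.columns) != list(traits.columns):
            raise ValueError("passive samples must share the active trait columns")
        passive_scores = pd.DataFrame(
            (np.asarray(passive, float) - grand) @ V,
            index=passive.index, columns=cols,
        )
    gm = pd.DataFrame(
        [active_scores[g == c].mean(axis=0) for c in classes],
        index=classes,
    )
    pct = 100.0 * eigvals / eigvals.sum() if eigvals.sum() > 0 else eigvals * 0
    return DiscriminantModel(
        coefficients=V, eigenvalues=eigvals, active_scores=active_scores,
        passive_scores=passive_scores, group_means=gm, grand_mean=grand,
        groups=classes, pct_discrimination=pct,
    )


@dataclass
class LooLdaResult:
    confusion: pd.DataFrame
    accuracy: float       # percentage
    accuracy_pct: int     # rounded for reporting


def loo_lda(
    traits: pd.DataFrame | np.ndarray,
    groups: Sequence[str],
    priors: str = "proportional",
) -> LooLdaResult:
    """Leave-one-out (jack-knifed) linear discriminant classification.

    Every sample is classified by an LDA fitted on all remaining samples
    (pooled covariance; group priors proportional to training group size, or
    uniform).  Returns the confusion matrix (rows = true groups) and overall
    accuracy.
    """
    X = np.asarray(traits, dtype=float)
    g = np.asarray(groups)
    classes = sorted(set(g))
    sizes = {c: int((g == c).sum()) for c in classes}
    small = [c for c, s in sizes.items() if s < 2]
    if small:
        raise ValueError(f"groups with a single sample cannot be jack-knifed: {small}")
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    n = len(X)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train_classes = sorted(set(g[mask]))
        pri = None
        if priors == "uniform":
            pri = np.full(len(train_classes), 1.0 / len(train_classes))
        lda = LinearDiscriminantAnalysis(priors=pri)
        lda.fit(X[mask], g[mask])
        pred = lda.predict(X[i:i + 1])[0]
        conf.loc[g[i], pred] += 1
    correct = int(np.trace(conf.values))
    acc = 100.0 * correct / n
    return LooLdaResult(confusion=conf, accuracy=acc,
                        accuracy_pct=int(round_half_up(acc, 0)))


def chained_impute(
    traits: pd.DataFrame,
    max_missing_frac: float = 0.5,
    n_iter: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Deterministic chained-equations imputation of a numeric trait table.

    Rows with strictly more than ``max_missing_frac`` missing cells are
    dropped.  Remaining missing cells start at column means and are updated
    by iterated per-column least-squares regressions on all other columns
    for ``n_iter`` sweeps.  Fully deterministic given the inputs (``seed``
    is accepted for interface stability; the deterministic variant ignores
    it).
    """
    df = traits.copy().astype(float)
    all_missing = [c for c in df.columns if df[c].isna().all()]
    if all_missing:
        raise ValueError(f"columns entirely missing: {all_missing}")
    frac = df.isna().mean(axis=1)
    df = df.loc[frac <= max_missing_frac].copy()
    mask = df.isna()
    if not mask.values.any():
        return df
    filled = df.fillna(df.mean())
    cols = list(df.columns)
    for _ in range(n_iter):
        for c in cols:
            miss = mask[c]
            if not miss.any():
                continue
            others = [o for o in cols if o != c]
            A = np.column_stack(
                [np.ones(len(filled)), filled[others].to_numpy()]
            )
            obs = ~miss.to_numpy()
            coef, *_ = np.linalg.lstsq(A[obs], filled.loc[obs, c].to_numpy(),
                                       rcond=None)
            filled.loc[miss, c] = A[miss.to_numpy()] @ coef
    return filled


@dataclass
class PCAResult:
    scores: pd.DataFrame
    pct_variance: np.ndarray
    loadings: pd.DataFrame


def pca_traits(traits: pd.DataFrame, scaled: bool = True) -> PCAResult:
    """PCA of a complete numeric trait table (correlation matrix when
    ``scaled``, which is the default for heterogeneous fruit traits)."""
    df = traits.astype(float)
    if df.isna().values.any():
        raise ValueError("trait table contains missing values; impute first")
    zero = [c for c in df.columns if df[c].std(ddof=1) == 0]
    if zero:
        raise ValueError(f"zero-variance columns: {zero}")
    X = df.to_numpy()
    X = X - X.mean(axis=0)
    if scaled:
        X = X / df.std(ddof=1).to_numpy()
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    var = S ** 2
    keep = var > 1e-12 * max(var.max(), 1.0)
    scores = (U * S)[:, keep]
    pct = 100.0 * var[keep] / var[keep].sum()
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=df.index, columns=cols),
        pct_variance=pct,
        loadings=pd.DataFrame(Vt[keep].T, index=df.columns, columns=cols),
    )
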