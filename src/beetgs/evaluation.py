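"""Prediction-accuracy assessment.

The central quantity is r_MP, the Pearson correlation between observed and
predicted phenotypes in a validation set, standardized to the accuracy of
predicting true breeding values by r_GS = r_MP / h where h is the square
root of entry-mean heritability.  Accuracy is assessed by repeated
fivefold cross-validation (fit marker effects on 80% of the lines, predict
the held-out 20%) and by across-population prediction (fit once on a
training population, e.g. a diversity set, and predict an independent
family).  Negative accuracies are reported with their sign: an opposite
marker-QTL linkage phase between training set and family genuinely
produces a negative prediction signal.

By default the ridge penalty and h come from variance components of the
full data (not re-estimated inside folds), matching the convention of
using entire-population estimates also for family subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .core import MarkerMatrix
from .pheno import VarianceComponents, heritability
from .rrblup import compute_lambda, fit_rrblup, predict

__all__ = [
    "CVScheme",
    "make_folds",
    "cross_validate",
    "across_population_predict",
    "training_size_sweep",
    "marker_density_sweep",
    "compare_cv_vs_across",
]


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation layout.

    ``mode="partition"`` (default): each repeat is one random k-fold
    partition, every line validated exactly once per repeat.
    ``mode="resample"``: each repeat is a single random (k-1)/k vs 1/k
    train/validation draw.  ``pooled=True`` computes one r per repeat over
    the pooled validation predictions instead of one r per fold.
    """

    k: int = 5
    repeats: int = 100
    seed: int = 0
    mode: str = "partition"
    pooled: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need k >= 2 folds")
        if self.mode not in ("partition", "resample"):
            raise ValueError("mode must be 'partition' or 'resample'")


def make_folds(n_or_ids, scheme: CVScheme) -> list[list[np.ndarray]]:
    """Seeded fold index sets, one list of k index arrays per repeat.

    Fold sizes differ by at most one (ceil(N/k) then floor(N/k)); folds
    partition the line set exactly.
    """
    n = n_or_ids if isinstance(n_or_ids, (int, np.integer)) else len(n_or_ids)
    if scheme.k > n:
        raise ValueError(f"k={scheme.k} folds but only {n} lines")
    rng = np.random.default_rng(scheme.seed)
    out = []
    for _ in range(scheme.repeats):
        perm = rng.permutation(n)
        if scheme.mode == "partition":
            out.append([np.sort(f) for f in np.array_split(perm, scheme.k)])
        else:
            out.append([np.sort(perm[: n // scheme.k])])
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _resolve_lam_h(vc, n_markers, lam, h):
    if lam is None:
        if vc is None:
            raise ValueError("supply either vc or an explicit lambda")
        lam = compute_lambda(vc, n_markers)
    if h is None:
        if vc is None:
            raise ValueError("supply either vc or an explicit h")
        h = float(np.sqrt(heritability(vc)))
    if not (0 < h <= 1.5):
        raise ValueError("h must be a positive square-root heritability")
    return float(lam), float(h)


def cross_validate(
    X,
    y,
    vc: VarianceComponents | None = None,
    scheme: CVScheme = CVScheme(),
    lam: float | None = None,
    h: float | None = None,
) -> pd.DataFrame:
    """Repeated k-fold cross-validated accuracy on BLUEs.

    Returns one row per repeat x fold (or per repeat when pooled) with
    columns ``repeat, fold, n_val, r_mp, h, r_gs``.  Validation folds with
    undefined correlation (zero variance) yield NaN with a warning.  The
    fit reuses sufficient statistics (X'X, X'y) of the full data, so each
    fold costs one dense ridge solve.
    """
    Z = X.X if isinstance(X, MarkerMatrix) else np.asarray(X, dtype=float)
    if np.isnan(Z).any():
        raise ValueError("marker matrix contains missing genotypes; impute first")
    y = np.asarray(y, dtype=float)
    n, m = Z.shape
    lam, h = _resolve_lam_h(vc, m, lam, h)

    G = Z.T @ Z
    Xty = Z.T @ y
    s = Z.sum(axis=0)
    sy = float(y.sum())

    rows = []
    n_undefined = 0
    for rep, folds in enumerate(make_folds(n, scheme)):
        pooled_obs, pooled_pred = [], []
        for fold_no, val in enumerate(folds):
            Zv = Z[val]
            yv = y[val]
            n_t = n - len(val)
            st = (s - Zv.sum(axis=0)) / n_t
            yt_mean = (sy - yv.sum()) / n_t
            A = G - Zv.T @ Zv - n_t * np.outer(st, st)
            A[np.diag_indices_from(A)] += lam
            rhs = (Xty - Zv.T @ yv) - n_t * st * yt_mean
            effects = cho_solve(cho_factor(A, lower=True), rhs)
            pv = Zv @ effects
            if scheme.pooled:
                pooled_obs.append(yv)
                pooled_pred.append(pv)
                continue
            r = _pearson(yv, pv)
            if np.isnan(r):
                n_undefined += 1
            rows.append((rep, fold_no, len(val), r, h, r / h))
        if scheme.pooled:
            obs = np.concatenate(pooled_obs)
            pred = np.concatenate(pooled_pred)
            r = _pearson(obs, pred)
            if np.isnan(r):
                n_undefined += 1
            rows.append((rep, -1, len(obs), r, h, r / h))
    if n_undefined:
        warnings.warn(f"{n_undefined} validation sets had undefined correlation "
                      "(zero variance); recorded as NaN", stacklevel=2)
    return pd.DataFrame(rows, columns=["repeat", "fold", "n_val", "r_mp", "h", "r_gs"])


def across_population_predict(
    X_train,
    y_train,
    X_test,
    y_test,
    vc: VarianceComponents | None = None,
    lam: float | None = None,
    h: float | None = None,
) -> pd.DataFrame:
    """Fit once on the training population, report accuracy on the test set.

    One result row (``r_mp, h, r_gs, n_train, n_test``).  The sign of the
    correlation is preserved; an all-monomorphic test set gives constant
    predictions and an undefined (NaN) correlation with a warning.
    """
    Zt = X_train.X if isinstance(X_train, MarkerMatrix) else np.asarray(X_train, float)
    Zs = X_test.X if isinstance(X_test, MarkerMatrix) else np.asarray(X_test, float)
    if Zt.shape[1] != Zs.shape[1]:
        raise ValueError("training and test marker columns are not aligned")
    if Zt.shape[0] < 2:
        raise ValueError("training population must contain >= 2 lines")
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    lam, h = _resolve_lam_h(vc, Zt.shape[1], lam, h)
    model = fit_rrblup(Zt, y_train, lam)
    pv = predict(model, Zs)
    r = _pearson(y_test, pv)
    if np.isnan(r):
        warnings.warn("test-set correlation undefined (constant predictions or "
                      "constant phenotypes)", stacklevel=2)
    return pd.DataFrame(
        [(r, h, r / h, Zt.shape[0], Zs.shape[0])],
        columns=["r_mp", "h", "r_gs", "n_train", "n_test"],
    )


def training_size_sweep(
    X_pool,
    y_pool,
    sizes,
    X_test,
    y_test,
    vc: VarianceComponents | None = None,
    repeats: int = 20,
    seed: int = 0,
    lam: float | None = None,
    h: float | None = None,
    nested: bool = False,
) -> pd.DataFrame:
    """Across-population accuracy as the training set is subsampled.

    Per size and repeat, a training subset is drawn without replacement
    from the pool, marker effects are re-fitted, and the test accuracy is
    recorded.  ``nested=True`` draws one permutation per repeat and uses
    prefixes, so smaller samples are subsets of larger ones.
    """
    Zp = X_pool.X if isinstance(X_pool, MarkerMatrix) else np.asarray(X_pool, float)
    yp = np.asarray(y_pool, dtype=float)
    sizes = sorted(int(s) for s in sizes)
    if sizes[0] < 2:
        raise ValueError("training sizes must be >= 2")
    if sizes[-1] > Zp.shape[0]:
        raise ValueError("largest size exceeds the pool")
    lam, h = _resolve_lam_h(vc, Zp.shape[1], lam, h)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        perm = rng.permutation(Zp.shape[0]) if nested else None
        for size in sizes:
            idx = perm[:size] if nested else rng.choice(Zp.shape[0], size, replace=False)
            res = across_population_predict(
                Zp[idx], yp[idx], X_test, y_test, lam=lam, h=h
            )
            rows.append((size, rep, float(res["r_mp"].iloc[0]), h,
                         float(res["r_gs"].iloc[0])))
    return pd.DataFrame(rows, columns=["size", "repeat", "r_mp", "h", "r_gs"])


def marker_density_sweep(
    X,
    y,
    vc: VarianceComponents,
    marker_counts,
    scheme: CVScheme = CVScheme(repeats=10),
    seed: int = 0,
    h: float | None = None,
) -> pd.DataFrame:
    """Cross-validated accuracy on random marker subsets of varying size.

    The penalty is recomputed for each subset size (lambda scales linearly
    with the number of fitted markers Nm).  Returns the per-fold results
    with a ``n_markers`` column.
    """
    Z = X.X if isinstance(X, MarkerMatrix) else np.asarray(X, dtype=float)
    m = Z.shape[1]
    counts = sorted(int(c) for c in marker_counts)
    if counts[0] < 1:
        raise ValueError("marker counts must be >= 1")
    if counts[-1] > m:
        raise ValueError("marker count exceeds available markers")
    rng = np.random.default_rng(seed)
    frames = []
    for c in counts:
        idx = np.sort(rng.choice(m, c, replace=False)) if c < m else np.arange(m)
        lam_c = compute_lambda(vc, c)
        res = cross_validate(Z[:, idx], y, scheme=scheme, lam=lam_c,
                             h=h if h is not None else float(np.sqrt(heritability(vc))))
        res.insert(0, "n_markers", c)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def compare_cv_vs_across(within_cv: dict, across: dict) -> pd.DataFrame:
    """Per-(family, trait) accuracy difference: across-population minus within-CV.

    Both arguments map ``(family, trait)`` keys to a summary accuracy
    (e.g. mean r_mp); keys must match exactly.
    """
    if set(within_cv) != set(across):
        diff = sorted(set(map(str, within_cv)) ^ set(map(str, across)))
        raise ValueError(f"unmatched (family, trait) keys: {diff[:10]}")
    rows = [
        (fam, trait, across[(fam, trait)], within_cv[(fam, trait)],
         across[(fam, trait)] - within_cv[(fam, trait)])
        for fam, trait in sorted(within_cv)
    ]
    return pd.DataFrame(rows, columns=["family", "trait", "r_across", "r_within_cv", "delta"])
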