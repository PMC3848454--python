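"""Ridge-regression BLUP: the genomic-prediction core.

The model is y = mu + sum_j X_j a_j + e with every marker fitted jointly
as a random effect of common variance sigma_G^2 / Nm.  The ridge penalty
is the variance ratio

    lambda = (sigma_e^2 / L) / (sigma_G^2 / Nm)

where sigma_e^2 / L is the error variance of an entry mean over L
locations.  Marker effects solve the mixed-model equations with the
intercept mu carried as an unpenalized fixed effect; absorbing mu is
equivalent to centering the dosage columns and the response, so

    a_hat = (Zc' Zc + lambda I)^{-1} Zc' yc,    mu_hat = ybar - zbar' a_hat

with Zc the column-centered dosage matrix.  When markers outnumber lines
the equivalent observation-space (kinship) system is solved instead:
a_hat = Zc' (Zc Zc' + lambda I)^{-1} yc.  Both routes give identical
solutions for lambda > 0; ``gblup_oracle`` exposes the kinship route
directly as an independent check.

Dosages are used raw (0-1-2), not centered or standardized, in the
reported predictions: PV_i = sum_j X_ij a_hat_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .core import MarkerMatrix
from .pheno import VarianceComponents

__all__ = [
    "GSModel",
    "impute_missing",
    "compute_lambda",
    "fit_rrblup",
    "predict",
    "gblup_oracle",
]


@dataclass
class GSModel:
    """Fitted RR-BLUP model: intercept, marker effects, penalty, metadata."""

    mu: float
    effects: np.ndarray
    lam: float
    marker_ids: np.ndarray
    train_marker_means: np.ndarray

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if len(self.effects) != len(self.marker_ids):
            raise ValueError("effects and marker_ids length mismatch")

    @property
    def n_markers(self) -> int:
        return len(self.effects)


def impute_missing(
    mm: MarkerMatrix,
    mode: str = "sample",
    seed: int | np.random.Generator | None = None,
) -> MarkerMatrix:
    """Fill missing dosages from each marker's observed genotype classes.

    mode "sample": each missing entry is drawn from the marker's observed
    0/1/2 class frequencies (the probabilistic imputation used for SNP
    panels); mode "mean": deterministic mean-dosage fill.  Observed
    entries are never altered.
    """
    if mode not in ("sample", "mean"):
        raise ValueError("mode must be 'sample' or 'mean'")
    if not mm.has_missing:
        return mm
    X = mm.X.copy()
    missing = np.isnan(X)
    all_missing = missing.all(axis=0)
    if all_missing.any():
        bad = mm.marker_ids[all_missing]
        raise ValueError(f"markers entirely missing, cannot impute: {list(bad)}")
    if mode == "mean":
        means = np.nanmean(X, axis=0)
        idx = np.where(missing)
        X[idx] = means[idx[1]]
    else:
        rng = np.random.default_rng(seed)
        for j in np.flatnonzero(missing.any(axis=0)):
            obs = X[~missing[:, j], j]
            classes, counts = np.unique(obs, return_counts=True)
            probs = counts / counts.sum()
            n_miss = int(missing[:, j].sum())
            X[missing[:, j], j] = rng.choice(classes, size=n_miss, p=probs)
    return MarkerMatrix(X, mm.line_ids, mm.marker_ids)


def compute_lambda(vc: VarianceComponents, n_markers: int) -> float:
    """Ridge penalty lambda = (sigma_e^2 / L) / (sigma_G^2 / Nm)."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    if vc.L_effective <= 0:
        raise ValueError("L_effective must be positive")
    if vc.sigma2_G <= 0:
        raise ValueError(
            "sigma_G^2 = 0 implies infinite shrinkage; the trait has no "
            "genotypic variance to predict"
        )
    return float((vc.sigma2_e / vc.L_effective) / (vc.sigma2_G / n_markers))


def _as_array(X) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(X, MarkerMatrix):
        if X.has_missing:
            raise ValueError("marker matrix contains missing genotypes; impute first")
        return X.X, X.marker_ids
    return np.asarray(X, dtype=float), None


def fit_rrblup(X, y, lam: float, marker_ids=None) -> GSModel:
    """Solve the penalized mixed-model equations for the marker effects.

    Picks the marker-space (Nm x Nm) or observation-space (N x N) system,
    whichever is smaller; the two are algebraically identical.  lambda = 0
    is only accepted when the centered dosage matrix has full column rank.
    """
    Z, ids = _as_array(X)
    if marker_ids is not None:
        ids = np.asarray(marker_ids, dtype=object)
    if ids is None:
        ids = np.array([f"m{j}" for j in range(Z.shape[1])], dtype=object)
    y = np.asarray(y, dtype=float)
    n, m = Z.shape
    if len(y) != n:
        raise ValueError("y length must equal number of lines")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    zbar = Z.mean(axis=0)
    Zc = Z - zbar
    ybar = float(y.mean())
    yc = y - ybar
    if lam == 0 and np.linalg.matrix_rank(Zc) < m:
        raise np.linalg.LinAlgError(
            "lambda = 0 with rank-deficient marker matrix: the ridge system "
            "is singular (more markers than independent lines)"
        )
    if m <= n:
        A = Zc.T @ Zc
        A[np.diag_indices_from(A)] += lam
        effects = cho_solve(cho_factor(A, lower=True), Zc.T @ yc)
    else:
        K = Zc @ Zc.T
        K[np.diag_indices_from(K)] += lam
        alpha = cho_solve(cho_factor(K, lower=True), yc)
        effects = Zc.T @ alpha
    mu = ybar - float(zbar @ effects)
    return GSModel(mu=mu, effects=effects, lam=float(lam), marker_ids=ids,
                   train_marker_means=zbar)


def predict(model: GSModel, X_new, marker_ids=None) -> np.ndarray:
    """Genetic values PV_i = sum_j X_ij a_hat_j over raw 0-1-2 dosages.

    The intercept is reported separately on the model; correlations with
    observed phenotypes are unaffected by it.
    """
    Z, ids = _as_array(X_new)
    if marker_ids is not None:
        ids = np.asarray(marker_ids, dtype=object)
    if ids is not None:
        if len(ids) != model.n_markers or not np.array_equal(ids, model.marker_ids):
            unmatched = sorted(set(map(str, ids)) ^ set(map(str, model.marker_ids)))
            raise ValueError(f"marker set mismatch with fitted model: {unmatched[:10]}")
    elif Z.shape[1] != model.n_markers:
        raise ValueError("marker count mismatch with fitted model")
    return Z @ model.effects


def gblup_oracle(X_train, y, lam: float, X_new) -> np.ndarray:
    """Kinship-space formulation of the same BLUP, for cross-checking.

    Builds the genomic kernel K = Zc Zc' / Nm on the training lines and
    predicts through the observation-space system with matched variance
    ratio lambda / Nm:

        PV = Z_new Zc' (Nm (K + (lambda/Nm) I))^{-1} yc

    which must agree with ``fit_rrblup`` + ``predict`` to solver precision
    for lambda > 0.
    """
    Z, _ = _as_array(X_train)
    Znew, _ = _as_array(X_new)
    y = np.asarray(y, dtype=float)
    n, m = Z.shape
    zbar = Z.mean(axis=0)
    Zc = Z - zbar
    yc = y - y.mean()
    K = (Zc @ Zc.T) / m
    A = m * (K + (lam / m) * np.eye(n))
    if lam == 0 and np.linalg.matrix_rank(A) < n:
        raise np.linalg.LinAlgError("singular observation-space system at lambda = 0")
    alpha = np.linalg.solve(A, yc)
    return (Znew @ Zc.T) @ alpha
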