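"""Phenotypic mixed-model stage.

Fits the per-location entry-mean model

    y_ij = mu + l_j + g_i + e_ij

with location (l_j) and genotype (g_i) as independent random effects and a
residual that absorbs genotype x location interaction (one observation per
line x location, so the two are confounded).  Variance components are
estimated by REML with the residual variance profiled out; the restricted
likelihood is evaluated exactly through the mixed-model equations, which
for this model reduce to a J x J solve (J = number of locations) because
the genotype block of the coefficient matrix is diagonal.

The module also provides the halved-P likelihood-ratio test for the
genotypic variance (the null value sits on the boundary of the parameter
space, so the naive chi-square P value is halved), entry-mean heritability
h^2 = sigma_G^2 / (sigma_G^2 + sigma_e^2 / L), and fixed-genotype BLUEs
with location kept random.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .core import PhenotypeRecords

__all__ = [
    "VarianceComponents",
    "fit_variance_components",
    "lrt_genotypic_variance",
    "halved_p",
    "heritability",
    "estimate_blues",
    "filter_min_locations",
]

logger = logging.getLogger(__name__)

_LOG_GAMMA_BOUNDS = (-30.0, 30.0)
_CLAMP_GAMMA = 1e-6  # variance ratios below this are reported as 0


@dataclass
class VarianceComponents:
    """REML variance components of the entry-mean model."""

    sigma2_G: float
    sigma2_L: float
    sigma2_e: float
    mu: float
    L_effective: float
    loglik: float
    n_obs: int
    n_lines: int
    n_locations: int
    converged: bool = True
    clamped: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# restricted-likelihood core


class _RemlCore:
    """Exact restricted likelihood for intercept + (location, genotype) randoms.

    Uses the Woodbury identity: with Z the random-effect design and
    Gamma = diag(gamma_L I_J, gamma_G I_N), H = I + Z Gamma Z' and
    M = Gamma^{-1} + Z'Z.  The genotype block of M is diagonal, so every
    evaluation costs one J x J Cholesky.
    """

    def __init__(self, y: np.ndarray, loc_codes: np.ndarray, line_codes: np.ndarray):
        self.y = y
        self.n = len(y)
        self.J = int(loc_codes.max()) + 1
        self.N = int(line_codes.max()) + 1
        self.dL = np.bincount(loc_codes, minlength=self.J).astype(float)
        self.dG = np.bincount(line_codes, minlength=self.N).astype(float)
        R = np.zeros((self.J, self.N))
        np.add.at(R, (loc_codes, line_codes), 1.0)
        self.R = R
        self.uL = np.bincount(loc_codes, weights=y, minlength=self.J)
        self.uG = np.bincount(line_codes, weights=y, minlength=self.N)
        self.sum_y = float(y.sum())
        self.yty = float(y @ y)

    # -- quadratic forms under H^{-1} for the three block configurations

    def _forms(self, gamma_L: float | None, gamma_G: float | None):
        """Returns (logdetH, xhx, xhy, yhy)."""
        n, sum_y, yty = self.n, self.sum_y, self.yty
        if gamma_L is None and gamma_G is None:
            return 0.0, float(n), sum_y, yty
        if gamma_L is None:  # genotype only
            a = self.dG + 1.0 / gamma_G
            logdetH = float(np.sum(np.log(gamma_G * a)))
            xhx = n - float(np.sum(self.dG**2 / a))
            xhy = sum_y - float(np.sum(self.dG * self.uG / a))
            yhy = yty - float(np.sum(self.uG**2 / a))
            return logdetH, xhx, xhy, yhy
        if gamma_G is None:  # location only
            a = self.dL + 1.0 / gamma_L
            logdetH = float(np.sum(np.log(gamma_L * a)))
            xhx = n - float(np.sum(self.dL**2 / a))
            xhy = sum_y - float(np.sum(self.dL * self.uL / a))
            yhy = yty - float(np.sum(self.uL**2 / a))
            return logdetH, xhx, xhy, yhy
        aG = self.dG + 1.0 / gamma_G
        inv_aG = 1.0 / aG
        S = np.diag(self.dL + 1.0 / gamma_L) - (self.R * inv_aG) @ self.R.T
        cho = cho_factor(S, lower=True)
        logdetM = float(np.sum(np.log(aG))) + 2.0 * float(
            np.sum(np.log(np.diag(cho[0])))
        )
        logdetH = logdetM + self.J * math.log(gamma_L) + self.N * math.log(gamma_G)

        def solve(rL, rG):
            xL = cho_solve(cho, rL - self.R @ (rG * inv_aG))
            xG = (rG - self.R.T @ xL) * inv_aG
            return xL, xG

        xL1, xG1 = solve(self.dL, self.dG)
        xL2, xG2 = solve(self.uL, self.uG)
        xhx = n - float(self.dL @ xL1 + self.dG @ xG1)
        xhy = sum_y - float(self.dL @ xL2 + self.dG @ xG2)
        yhy = yty - float(self.uL @ xL2 + self.uG @ xG2)
        return logdetH, xhx, xhy, yhy

    def neg2_reml(self, gamma_L: float | None, gamma_G: float | None) -> float:
        logdetH, xhx, xhy, yhy = self._forms(gamma_L, gamma_G)
        ypy = yhy - xhy**2 / xhx
        df = self.n - 1
        sigma2e = max(ypy / df, 1e-300)
        return df * (math.log(2 * math.pi * sigma2e) + 1.0) + logdetH + math.log(xhx)

    def solution(self, gamma_L: float | None, gamma_G: float | None):
        """(mu, sigma2_e, restricted loglik) at the given variance ratios."""
        logdetH, xhx, xhy, yhy = self._forms(gamma_L, gamma_G)
        ypy = yhy - xhy**2 / xhx
        df = self.n - 1
        sigma2e = max(ypy / df, 1e-300)
        mu = xhy / xhx
        neg2 = df * (math.log(2 * math.pi * sigma2e) + 1.0) + logdetH + math.log(xhx)
        return mu, sigma2e, -0.5 * neg2


def _moment_init(core: _RemlCore, use_loc: bool) -> tuple[float, float]:
    """ANOVA-style moment starting values for (gamma_L, gamma_G).

    Exact for balanced one-observation-per-cell tables, a rough but
    harmless start otherwise.
    """
    y, n = core.y, core.n
    grand = core.sum_y / n
    sst = core.yty - n * grand**2
    line_means = core.uG / core.dG
    ssg = float(np.sum(core.dG * (line_means - grand) ** 2))
    c_line = n / core.N
    if use_loc:
        loc_means = core.uL / core.dL
        ssl = float(np.sum(core.dL * (loc_means - grand) ** 2))
        sse = max(sst - ssg - ssl, 1e-12)
        dfe = max((core.N - 1) * (core.J - 1), 1)
        mse = sse / dfe
        msl = ssl / max(core.J - 1, 1)
        sG = max((ssg / max(core.N - 1, 1) - mse) / c_line, 0.0)
        sL = max((msl - mse) / (n / core.J), 0.0)
        gG = sG / mse if mse > 0 else 1.0
        gL = sL / mse if mse > 0 else 1.0
    else:
        sse = max(sst - ssg, 1e-12)
        mse = sse / max(n - core.N, 1)
        sG = max((ssg / max(core.N - 1, 1) - mse) / c_line, 0.0)
        gG = sG / mse if mse > 0 else 1.0
        gL = 0.0
    return max(gL, 1e-3), max(gG, 1e-3)


def _optimize(core: _RemlCore, use_loc: bool, use_line: bool):
    """Maximize the restricted likelihood over the active log-ratios."""
    lo, hi = _LOG_GAMMA_BOUNDS
    if not use_loc and not use_line:
        mu, s2e, ll = core.solution(None, None)
        return None, None, mu, s2e, ll, True
    gL0, gG0 = _moment_init(core, use_loc)

    def unpack(t):
        t = np.clip(t, lo, hi)
        i = 0
        gL = gG = None
        if use_loc:
            gL = math.exp(t[i]); i += 1
        if use_line:
            gG = math.exp(t[i])
        return gL, gG

    def objective(t):
        return core.neg2_reml(*unpack(t))

    x0 = []
    if use_loc:
        x0.append(math.log(max(gL0, 1e-4)))
    if use_line:
        x0.append(math.log(max(gG0, 1e-4)))
    res = optimize.minimize(
        objective,
        np.array(x0),
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 4000, "maxfev": 4000},
    )
    gL, gG = unpack(res.x)
    mu, s2e, ll = core.solution(gL, gG)
    return gL, gG, mu, s2e, ll, bool(res.success)


# ---------------------------------------------------------------------------
# public operations


def _prepare(records: PhenotypeRecords):
    df = records.df
    y = df["value"].to_numpy(dtype=float)
    line_codes, line_ids = pd.factorize(df["line_id"])
    loc_codes, loc_ids = pd.factorize(df["location_id"])
    return y, line_codes, loc_codes, line_ids, loc_ids


def _check_connected(line_codes: np.ndarray, loc_codes: np.ndarray, n_lines: int, n_locs: int):
    """Union-find over the bipartite line-location incidence graph."""
    parent = list(range(n_lines + n_locs))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for li, lo in zip(line_codes, loc_codes):
        ra, rb = find(li), find(n_lines + lo)
        if ra != rb:
            parent[ra] = rb
    roots = {find(n_lines + j) for j in range(n_locs)}
    if len(roots) > 1:
        raise ValueError("trial design is disconnected: locations share no lines")


def effective_locations(records: PhenotypeRecords, convention: str = "harmonic") -> float:
    """Summary location count L entering h^2 and the ridge penalty.

    "harmonic" (default) is the harmonic mean of per-line distinct-location
    counts — the count that makes sigma_e^2 / L the average variance of a
    line mean; "arithmetic" is the plain mean; "total" is the number of
    distinct locations in the trial.
    """
    counts = records.locations_per_line().to_numpy(dtype=float)
    if convention == "harmonic":
        return float(1.0 / np.mean(1.0 / counts))
    if convention == "arithmetic":
        return float(np.mean(counts))
    if convention == "total":
        return float(records.df["location_id"].nunique())
    raise ValueError(f"unknown L convention: {convention}")


def fit_variance_components(
    records: PhenotypeRecords,
    l_convention: str = "harmonic",
) -> VarianceComponents:
    """REML estimates of (sigma_G^2, sigma_L^2, sigma_e^2) and the intercept.

    Estimates at the boundary are clamped to zero and flagged in
    ``clamped``.  Raises for designs where the genotypic and residual
    variances are not separable (single location and one record per line).
    """
    y, line_codes, loc_codes, line_ids, loc_ids = _prepare(records)
    n, N, J = len(y), len(line_ids), len(loc_ids)
    if N < 2 or n < 2:
        raise ValueError("need at least two lines and two records")
    if J == 1 and n == N:
        raise ValueError(
            "sigma_G^2 and sigma_e^2 are unidentifiable: single location with "
            "one record per line"
        )
    if J > 1:
        _check_connected(line_codes, loc_codes, N, J)
    core = _RemlCore(y, loc_codes, line_codes)
    use_loc = J > 1
    gL, gG, mu, s2e, ll, ok = _optimize(core, use_loc, use_line=True)

    clamped = []
    sigma2_L = (gL or 0.0) * s2e
    sigma2_G = (gG or 0.0) * s2e
    if use_loc and gL is not None and gL < _CLAMP_GAMMA:
        sigma2_L = 0.0
        clamped.append("sigma2_L")
    if gG is not None and gG < _CLAMP_GAMMA:
        sigma2_G = 0.0
        clamped.append("sigma2_G")
    return VarianceComponents(
        sigma2_G=float(sigma2_G),
        sigma2_L=float(sigma2_L),
        sigma2_e=float(s2e),
        mu=float(mu),
        L_effective=effective_locations(records, l_convention),
        loglik=float(ll),
        n_obs=n,
        n_lines=N,
        n_locations=J,
        converged=ok,
        clamped=tuple(clamped),
    )


def halved_p(statistic: float) -> float:
    """Halved chi-square(1) upper-tail P for a boundary LRT statistic."""
    return 0.5 * float(stats.chi2.sf(statistic, df=1))


def lrt_genotypic_variance(records: PhenotypeRecords) -> tuple[float, float]:
    """Likelihood-ratio test of sigma_G^2 = 0 with the halved-P convention.

    Returns (statistic, halved P).  The statistic is floored at 0 (the
    reduced model is nested in the full one).
    """
    y, line_codes, loc_codes, line_ids, loc_ids = _prepare(records)
    n, N, J = len(y), len(line_ids), len(loc_ids)
    if N < 2 or n < 2:
        raise ValueError("need at least two lines and two records")
    if J == 1 and n == N:
        raise ValueError("genotypic variance untestable: no within-line replication")
    core = _RemlCore(y, loc_codes, line_codes)
    use_loc = J > 1
    *_, ll_full, ok_full = _optimize(core, use_loc, use_line=True)
    *_, ll_red, ok_red = _optimize(core, use_loc, use_line=False)
    if not (ok_full and ok_red):
        raise RuntimeError("REML did not converge for the full and/or reduced model")
    stat = max(0.0, 2.0 * (ll_full - ll_red))
    return stat, halved_p(stat)


def heritability(vc: VarianceComponents) -> float:
    """Entry-mean heritability h^2 = sigma_G^2 / (sigma_G^2 + sigma_e^2 / L)."""
    if vc.L_effective <= 0:
        raise ValueError("L_effective must be positive")
    denom = vc.sigma2_G + vc.sigma2_e / vc.L_effective
    if denom <= 0:
        raise ValueError("sigma_G^2 + sigma_e^2 / L must be positive")
    return float(vc.sigma2_G / denom)


def estimate_blues(records: PhenotypeRecords) -> pd.Series:
    """Fixed-genotype BLUEs across locations, location kept random.

    Fits y = g_i (fixed, cell-means coding) + l_j (random) + e by REML on
    the location variance ratio and returns the GLS genotype estimates,
    one adjusted mean per line.  With a single location the raw entry
    means are returned unchanged.
    """
    y, line_codes, loc_codes, line_ids, loc_ids = _prepare(records)
    n, N, J = len(y), len(line_ids), len(loc_ids)
    if J == 1:
        vals = pd.Series(y).groupby(line_codes).mean().to_numpy()
        return pd.Series(vals, index=pd.Index(line_ids, name="line_id"), name="blue")
    if n <= N:
        raise ValueError("BLUE estimation needs more records than lines "
                         "(some line must appear at >1 location)")
    _check_connected(line_codes, loc_codes, N, J)

    dL = np.bincount(loc_codes, minlength=J).astype(float)
    dG = np.bincount(line_codes, minlength=N).astype(float)
    B = np.zeros((N, J))
    np.add.at(B, (line_codes, loc_codes), 1.0)
    uL = np.bincount(loc_codes, weights=y, minlength=J)
    uG = np.bincount(line_codes, weights=y, minlength=N)
    yty = float(y @ y)
    df = n - N

    def pieces(gamma: float):
        a = dL + 1.0 / gamma  # (J,)
        xhx = np.diag(dG) - (B / a) @ B.T
        xhy = uG - B @ (uL / a)
        yhy = yty - float(np.sum(uL**2 / a))
        cho = cho_factor(xhx, lower=True)
        beta = cho_solve(cho, xhy)
        ypy = yhy - float(xhy @ beta)
        logdet_xhx = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        logdetH = float(np.sum(np.log(gamma * a)))
        return beta, ypy, logdetH, logdet_xhx

    def neg2(t: float) -> float:
        _, ypy, logdetH, logdet_xhx = pieces(math.exp(np.clip(t, *_LOG_GAMMA_BOUNDS)))
        s2e = max(ypy / df, 1e-300)
        return df * (math.log(2 * math.pi * s2e) + 1.0) + logdetH + logdet_xhx

    res = optimize.minimize_scalar(
        neg2, bounds=_LOG_GAMMA_BOUNDS, method="bounded",
        options={"xatol": 1e-8},
    )
    beta, *_ = pieces(math.exp(res.x))
    return pd.Series(beta, index=pd.Index(line_ids, name="line_id"), name="blue")


def filter_min_locations(records: PhenotypeRecords, k: int) -> PhenotypeRecords:
    """Keep only lines phenotyped at >= k distinct locations."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = records.locations_per_line()
    keep = counts.index[counts >= k]
    if len(keep) == 0:
        raise ValueError(f"no line was evaluated at >= {k} locations")
    dropped = len(counts) - len(keep)
    if dropped:
        logger.info("filter_min_locations(k=%d): dropped %d of %d lines", k, dropped, len(counts))
    return records.subset_lines(keep.to_numpy())
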