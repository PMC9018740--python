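"""Leave-one-out model comparison by Pareto-smoothed importance sampling.

For each scenario the pointwise log-likelihood matrix (posterior draws
× observations) yields the expected log pointwise predictive density
(elpd) of exact leave-one-out cross-validation, estimated by importance
sampling with the raw ratios 1/p(y_i | θ_s).  The heavy right tail of
those ratios is stabilised by fitting a generalized Pareto distribution
(GPD) to the largest M = ceil(min(0.2·S, 3·√S)) ratios and replacing
them with expected order statistics of the fit, truncated at the raw
maximum; the fitted shape parameter k diagnoses reliability (k > 0.7 is
flagged).  Scenario weights are stacking weights: the convex
combination of the scenarios' LOO predictive densities that maximises
the summed log score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .atmosphere import AtmosphericRecord
from .forward import CohortSolver
from .model import PosteriorChains
from .samples import SubjectSample

__all__ = [
    "PointwiseLogLik",
    "pointwise_loglik",
    "psis_smooth",
    "LooResult",
    "elpd_loo",
    "model_weights",
    "LooComparison",
    "compare",
]

PARETO_K_WARN = 0.7


@dataclass(frozen=True)
class PointwiseLogLik:
    """Per-draw (rows) per-observation (columns) log-likelihood terms."""

    matrix: np.ndarray
    scenario: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("pointwise log-likelihood must be a 2-D matrix")
        if not np.isfinite(m).all():
            bad = np.argwhere(~np.isfinite(m))[0]
            raise ValueError(
                f"non-finite log-likelihood at draw {bad[0]}, observation {bad[1]}"
            )
        object.__setattr__(self, "matrix", m)

    @property
    def n_draws(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[1]

    def row_sums(self) -> np.ndarray:
        """Total log-likelihood per draw (additivity over observations)."""
        return self.matrix.sum(axis=1)


def pointwise_loglik(
    chains: PosteriorChains,
    samples: Sequence[SubjectSample],
    record: AtmosphericRecord,
    *,
    thin: int = 1,
    solver: Optional[CohortSolver] = None,
) -> PointwiseLogLik:
    """Per-observation Gaussian log-likelihood terms for retained draws.

    ``thin`` keeps every ``thin``-th step of each walker (1 = all
    draws, S = walkers × retained steps).
    """
    from .scenarios import get_scenario

    if solver is None:
        solver = CohortSolver(samples, record)
    if len(samples) != len(solver.samples):
        raise ValueError("samples inconsistent with solver")
    param_class = get_scenario(chains.scenario)
    draws = chains.draws[:, ::thin, :].reshape(-1, chains.draws.shape[-1])
    obs = np.array([s.delta14c_permil for s in samples])
    out = np.empty((draws.shape[0], len(samples)))
    log_2pi = np.log(2.0 * np.pi)
    for s_idx, theta in enumerate(draws):
        params = param_class(**dict(zip(chains.param_names, theta)))
        pred = solver.predict(params)
        z = (obs - pred) / params.sigma
        out[s_idx] = -0.5 * z**2 - np.log(params.sigma) - 0.5 * log_2pi
    return PointwiseLogLik(matrix=out, scenario=chains.scenario)


# ---------------------------------------------------------------------------
# PSIS
# ---------------------------------------------------------------------------


def _gpd_fit_pwm(exceedances: np.ndarray) -> tuple[float, float]:
    """Probability-weighted-moments fit of the generalized Pareto.

    Returns (k, sigma) for the GPD with survival function
    (1 + k·y/σ)^(−1/k), i.e. k > 0 is a heavy (Pareto-like) tail.
    The PWM estimators of Hosking & Wallis use the opposite sign
    convention, hence the flip at the end.
    """
    y = np.sort(exceedances)
    n = y.size
    a0 = y.mean()
    # a1 = E[Y · (1-F(Y))] estimated with plotting-position weights
    w = (n - 1 - np.arange(n)) / (n - 1) if n > 1 else np.array([0.5])
    a1 = np.mean(w * y)
    denom = a0 - 2.0 * a1
    if denom <= 0:
        # sample moments inconsistent with any GPD of finite mean;
        # saturate at a very heavy tail
        return 1.5, float(max(a0, np.finfo(float).tiny))
    k = 2.0 - a0 / denom
    sigma = 2.0 * a0 * a1 / denom
    return float(k), float(max(sigma, np.finfo(float).tiny))


def _gpd_quantile(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma / k * (np.power(1.0 - p, -k) - 1.0)


def psis_smooth(log_ratios: np.ndarray) -> tuple[np.ndarray, float]:
    """Pareto-smooth a vector of importance log-ratios.

    Fits a GPD to the M = ceil(min(0.2·S, 3·√S)) largest ratios
    (probability-weighted moments, located at the M-th largest value),
    replaces them with expected order statistics of the fit, truncates
    at the raw maximum and normalises.

    Returns (weights, k): normalised importance weights summing to 1
    and the fitted Pareto shape.  Degenerate all-equal ratios give
    uniform weights and k = −inf.
    """
    lr = np.asarray(log_ratios, dtype=float)
    S = lr.size
    if S < 25:
        raise ValueError("need at least 25 importance ratios for PSIS")
    if not np.isfinite(lr).all():
        raise ValueError("log-ratios must be finite")
    if np.ptp(lr) < 1e-14:
        return np.full(S, 1.0 / S), -np.inf

    lr = lr - lr.max()  # stabilise; weights are normalised later
    M = int(np.ceil(min(0.2 * S, 3.0 * np.sqrt(S))))
    order = np.argsort(lr)
    tail_idx = order[-M:]
    cutoff = lr[order[-M - 1]] if S > M else lr[order[0]]

    x_tail = np.exp(lr[tail_idx])
    x_cut = np.exp(cutoff)
    exceed = x_tail - x_cut
    if np.ptp(exceed) < 1e-14:
        return _normalise(lr), -np.inf

    k, sigma = _gpd_fit_pwm(exceed)
    # expected order statistics of the fitted GPD at plotting positions
    p = (np.arange(1, M + 1) - 0.5) / M
    smoothed = x_cut + _gpd_quantile(p, k, sigma)
    smoothed = np.minimum(smoothed, np.exp(lr.max()))  # truncate at raw max (=1)
    # place smoothed values back in ascending order of the raw tail
    rank = np.argsort(lr[tail_idx])
    new_lr = lr.copy()
    new_lr[tail_idx[rank]] = np.log(smoothed)
    return _normalise(new_lr), float(k)


def _normalise(lr: np.ndarray) -> np.ndarray:
    w = np.exp(lr - logsumexp(lr))
    return w / w.sum()


# ---------------------------------------------------------------------------
# elpd
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LooResult:
    """PSIS-LOO estimate for one scenario."""

    scenario: str
    elpd: float
    se: float
    pointwise: np.ndarray  # elpd_i per observation
    pareto_k: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.pointwise.size

    @property
    def n_bad_k(self) -> int:
        return int(np.sum(self.pareto_k > PARETO_K_WARN))


def elpd_loo(pll: PointwiseLogLik) -> LooResult:
    """PSIS-LOO expected log pointwise predictive density.

    Per observation i the importance ratios are 1/p(y_i | θ_s), i.e.
    log-ratios −ll_{s,i}; elpd_i = log Σ_s w_{s,i} p(y_i | θ_s).  The
    standard error is √(n · var(elpd_i)).  Observations with Pareto
    k > 0.7 trigger a warning but the value is still returned.
    """
    ll = pll.matrix
    n = pll.n_obs
    pointwise = np.empty(n)
    ks = np.empty(n)
    for i in range(n):
        w, k = psis_smooth(-ll[:, i])
        pointwise[i] = logsumexp(ll[:, i], b=w)
        ks[i] = k
    if np.any(ks > PARETO_K_WARN):
        warnings.warn(
            f"{int(np.sum(ks > PARETO_K_WARN))} observation(s) with Pareto k > "
            f"{PARETO_K_WARN}; PSIS-LOO may be unreliable for them",
            RuntimeWarning,
        )
    elpd = float(pointwise.sum())
    se = float(np.sqrt(n * np.var(pointwise)))
    return LooResult(
        scenario=pll.scenario, elpd=elpd, se=se, pointwise=pointwise, pareto_k=ks
    )


def lppd(pll: PointwiseLogLik) -> float:
    """In-sample log pointwise predictive density (no leave-one-out)."""
    S = pll.n_draws
    return float(np.sum(logsumexp(pll.matrix, axis=0) - np.log(S)))


# ---------------------------------------------------------------------------
# scenario weights
# ---------------------------------------------------------------------------


def model_weights(
    loos: Sequence[LooResult],
    *,
    method: str = "stacking",
    seed: Optional[int] = None,
) -> np.ndarray:
    """Scenario weights from per-scenario LOO results.

    ``stacking`` (default) maximises the summed log score of the convex
    combination of LOO predictive densities over the simplex — the
    weights interpretable as the probability of each scenario being the
    best-predicting one.  ``pseudo-bma`` exponentiates elpd differences
    with a Bayesian-bootstrap (seeded) estimate of their variability
    ("pseudo-BMA+").
    """
    if len(loos) < 2:
        raise ValueError("need at least two scenarios to weight")
    n = loos[0].n_obs
    if any(l.n_obs != n for l in loos):
        raise ValueError("scenarios were evaluated on different observation sets")
    lpd = np.column_stack([l.pointwise for l in loos])  # (n, K)

    if method == "stacking":
        return _stacking_weights(lpd)
    if method == "pseudo-bma":
        return _pseudo_bma_plus(lpd, seed=0 if seed is None else seed)
    raise ValueError("method must be 'stacking' or 'pseudo-bma'")


def _stacking_weights(lpd: np.ndarray) -> np.ndarray:
    n, K = lpd.shape
    # work with densities normalised per observation for conditioning
    shift = lpd.max(axis=1, keepdims=True)
    dens = np.exp(lpd - shift)

    def neg_score(w):
        mix = dens @ w
        return -np.sum(np.log(np.maximum(mix, 1e-300)))

    def grad(w):
        mix = dens @ w
        return -(dens / np.maximum(mix, 1e-300)[:, None]).sum(axis=0)

    w0 = np.full(K, 1.0 / K)
    res = minimize(
        neg_score,
        w0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * K,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 2000, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0.0, 1.0)
    return w / w.sum()


def _pseudo_bma_plus(lpd: np.ndarray, seed: int, n_boot: int = 1000) -> np.ndarray:
    n, K = lpd.shape
    rng = np.random.default_rng(seed)
    alpha = rng.dirichlet(np.ones(n), size=n_boot)  # Bayesian bootstrap
    elpd_boot = n * (alpha @ lpd)  # (n_boot, K)
    z = elpd_boot - elpd_boot.max(axis=1, keepdims=True)
    w = np.exp(z)
    w /= w.sum(axis=1, keepdims=True)
    return w.mean(axis=0)


# ---------------------------------------------------------------------------
# comparison table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LooComparison:
    """Per-scenario elpd, diagnostics and weights (weights sum to 1)."""

    table: pd.DataFrame  # index scenario; columns elpd_loo, se, n_bad_k, weight
    loos: tuple

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.4g}")

    @property
    def best(self) -> str:
        return str(self.table["weight"].idxmax())

    def to_dict(self) -> dict:
        out = {
            row.Index: {
                "elpd_loo": float(row.elpd_loo),
                "se": float(row.se),
                "n_bad_k": int(row.n_bad_k),
                "weight": float(row.weight),
            }
            for row in self.table.itertuples()
        }
        return out


def compare(loos: Sequence[LooResult], *, method: str = "stacking") -> LooComparison:
    """Assemble the scenario comparison: elpd table plus weights."""
    w = model_weights(loos, method=method)
    table = pd.DataFrame(
        {
            "elpd_loo": [l.elpd for l in loos],
            "se": [l.se for l in loos],
            "n_bad_k": [l.n_bad_k for l in loos],
            "weight": w,
        },
        index=[l.scenario for l in loos],
    ).sort_values("weight", ascending=False)
    return LooComparison(table=table, loos=tuple(loos))
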