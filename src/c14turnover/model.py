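"""Bayesian estimation of turnover-scenario parameters.

The measurement model is additive Gaussian: an observed genomic Δ¹⁴C
value c_i deviates from the forward-model prediction c̄_i(d_i − b_i) by
noise of common SD σ, which absorbs both biological subject-to-subject
variability and AMS measurement error.  Priors are uniform in log-rate
for turnover rates on [1e−6, 0.5] /year, uniform on [0, 1] for the
renewing fraction f and uniform on [0, 100] ‰ for σ.

Sampling uses the affine-invariant ensemble ("stretch move") sampler of
emcee with 50 walkers per parameter, a 1000-step burn-in and 2000
retained steps; walkers are initialised from the prior.  Point
estimates are posterior medians; "one sigma" intervals are the
16th/84th percentiles of the marginals.

Usage follows the Model/Results pattern::

    model = TurnoverModel(samples, record, scenario="2POP")
    res = model.fit(seed=7)
    print(res.summary())
    res.population_turnover()       # posterior of f·β (2POP only)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import emcee
import numpy as np
import pandas as pd
from scipy import stats

from .atmosphere import AtmosphericRecord
from .forward import CohortSolver, default_max_step
from .samples import SubjectSample
from .scenarios import ScenarioParams, get_scenario, params_to_dict

__all__ = [
    "TurnoverModel",
    "TurnoverResults",
    "PosteriorChains",
    "PosteriorSummary",
    "log_likelihood",
    "log_prior",
    "run_mcmc",
    "summarize",
    "population_turnover",
    "fit_individual_rates",
]

_LOG_2PI = np.log(2.0 * np.pi)

#: default sampling protocol: walkers per parameter, burn-in, retained steps
WALKERS_PER_PARAM = 50
N_BURN = 1000
N_KEEP = 2000

#: an ensemble whose mean acceptance falls below this is flagged stuck
MIN_ACCEPTANCE = 0.05
RHAT_WARN = 1.05


# ---------------------------------------------------------------------------
# likelihood / prior as plain functions (natural parameter units)
# ---------------------------------------------------------------------------


def log_likelihood(
    params: ScenarioParams,
    samples: Sequence[SubjectSample],
    record: AtmosphericRecord,
    **solver_kw,
) -> float:
    """Gaussian log-likelihood of the cohort under a scenario.

    Σ_i [ −log(σ√(2π)) − ½((c_i − c̄_i)/σ)² ]; returns −inf for σ ≤ 0
    (a rejected state, not an error).
    """
    if params.sigma <= 0:
        return -np.inf
    solver_kw.setdefault("max_step", default_max_step(params.scenario))
    solver = CohortSolver(samples, record, **solver_kw)
    obs = np.array([s.delta14c_permil for s in samples])
    pred = solver.predict(params)
    resid = (obs - pred) / params.sigma
    return float(
        -0.5 * np.sum(resid**2) - len(samples) * (np.log(params.sigma) + 0.5 * _LOG_2PI)
    )


def log_prior(params: ScenarioParams) -> float:
    """Log prior density in the sampling coordinates, up to a constant.

    The sampler works in (log-rate, f, σ) coordinates where every prior
    is uniform, so the density is 0 inside the support and −inf outside.
    Rates therefore have equal prior density at e.g. 0.01 and 0.1 /year
    (log-uniform).
    """
    try:
        theta = params.to_sampled()
        lo, hi = params.sampled_bounds()
    except AttributeError:
        raise TypeError(f"unsupported scenario parameters: {params!r}")
    if np.all(theta >= lo) and np.all(theta <= hi):
        return 0.0
    return -np.inf


# ---------------------------------------------------------------------------
# chain containers
# ---------------------------------------------------------------------------


@dataclass
class PosteriorChains:
    """Retained MCMC draws with walker/step structure.

    ``draws`` holds natural-unit parameter values, shaped
    (walkers, steps, parameters) with parameter order ``param_names``.
    """

    scenario: str
    param_names: tuple
    draws: np.ndarray
    n_burn: int
    n_keep: int
    seed: int
    acceptance_fraction: float = np.nan
    max_rhat: float = np.nan
    stuck: bool = False

    @property
    def n_walkers(self) -> int:
        return self.draws.shape[0]

    def flat(self) -> np.ndarray:
        """Draws flattened over walkers and steps: (S, parameters)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: walker, step, parameter, value."""
        w, s, p = self.draws.shape
        walker, step, param = np.meshgrid(
            np.arange(w), np.arange(s), np.arange(p), indexing="ij"
        )
        return pd.DataFrame(
            {
                "walker": walker.ravel(),
                "step": step.ravel(),
                "parameter": np.array(self.param_names)[param.ravel()],
                "value": self.draws.ravel(),
            }
        )


@dataclass
class PosteriorSummary:
    """Median and 16/84-percentile bounds per parameter (and derived)."""

    table: pd.DataFrame  # index: name; columns: median, lower_1sig, upper_1sig

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.6g}")

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]


def summarize(chains: PosteriorChains) -> PosteriorSummary:
    """Posterior medians and 16th/84th percentiles over flattened draws."""
    flat = chains.flat()
    if flat.size == 0:
        raise ValueError("empty chains")
    q = np.percentile(flat, [16, 50, 84], axis=0)
    table = pd.DataFrame(
        {"median": q[1], "lower_1sig": q[0], "upper_1sig": q[2]},
        index=list(chains.param_names),
    )
    return PosteriorSummary(table)


def population_turnover(chains: PosteriorChains):
    """Posterior of the whole-population turnover f·β under 2POP.

    Returns (draws, summary): per-draw products and their
    median/16/84 summary, in /year.
    """
    if chains.scenario != "2POP":
        raise ValueError("population_turnover is defined for the 2POP scenario only")
    flat = chains.flat()
    i_beta = chains.param_names.index("beta")
    i_f = chains.param_names.index("f")
    prod = flat[:, i_f] * flat[:, i_beta]
    q = np.percentile(prod, [16, 50, 84])
    summary = PosteriorSummary(
        pd.DataFrame(
            {"median": [q[1]], "lower_1sig": [q[0]], "upper_1sig": [q[2]]},
            index=["f_beta"],
        )
    )
    return prod, summary


def _split_rhat(chain: np.ndarray) -> float:
    """Rank-normalised split-R̂ over walkers, max across parameters.

    ``chain`` is (walkers, steps, parameters); walkers play the role of
    chains.
    """
    import arviz as az

    posterior = {f"p{j}": chain[:, :, j] for j in range(chain.shape[2])}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.rhat(az.from_dict(posterior=posterior))
    vals = np.array([float(ds[k]) for k in posterior])
    return float(np.nanmax(vals))


def run_mcmc(
    scenario: str,
    samples: Sequence[SubjectSample],
    record: AtmosphericRecord,
    seed: int,
    *,
    n_walkers: Optional[int] = None,
    n_burn: int = N_BURN,
    n_keep: int = N_KEEP,
    lag_initial_condition: bool = True,
    max_step: Optional[float] = None,
    progress: bool = False,
) -> PosteriorChains:
    """Sample the posterior for one scenario with the ensemble sampler.

    Defaults follow the reference protocol: 50 walkers per parameter
    initialised from the prior, 1000 burn-in steps discarded, 2000
    retained.  Reproducible bit-for-bit under a fixed seed.
    """
    model = TurnoverModel(
        samples,
        record,
        scenario=scenario,
        lag_initial_condition=lag_initial_condition,
        max_step=max_step,
    )
    res = model.fit(
        seed=seed, n_walkers=n_walkers, n_burn=n_burn, n_keep=n_keep, progress=progress
    )
    return res.chains


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class TurnoverModel:
    """Turnover scenario fitted to a cohort of Δ¹⁴C measurements.

    Parameters
    ----------
    samples
        Measurements entering the likelihood (after any population
        filtering — see ``from_dataframe``).
    record
        Atmospheric Δ¹⁴C record covering every sample's life span.
    scenario
        "A", "LIN" or "2POP".
    lag_initial_condition
        Apply the food-chain lag to the birth value as well as the
        source term (default True).
    max_step
        Integration step ceiling in years; default is scenario-aware
        (knot-only grid for A/2POP where the stepper is exact, 0.25 y
        for LIN).
    """

    def __init__(
        self,
        samples: Sequence[SubjectSample],
        record: AtmosphericRecord,
        scenario: str = "A",
        *,
        lag_initial_condition: bool = True,
        max_step: Optional[float] = None,
    ) -> None:
        if len(samples) == 0:
            raise ValueError("need at least one sample")
        self.samples = list(samples)
        self.record = record
        self.param_class = get_scenario(scenario)
        self.scenario = self.param_class.scenario
        if max_step is None:
            max_step = default_max_step(self.scenario)
        self.solver = CohortSolver(
            self.samples,
            record,
            lag_initial_condition=lag_initial_condition,
            max_step=max_step,
        )
        self._obs = np.array([s.delta14c_permil for s in self.samples])
        self._lo, self._hi = self.param_class.sampled_bounds()
        self.ndim = len(self.param_class.param_names)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        record: AtmosphericRecord,
        scenario: str = "A",
        *,
        population: Optional[str] = "neuronal",
        **kw,
    ) -> "TurnoverModel":
        """Build from a measurement table (same schema as the CSV).

        ``population`` filters rows by cell population; pass None to
        fit neuronal and non-neuronal measurements jointly.
        """
        from .samples import SubjectSample

        if population is not None:
            df = df[df["population"] == population]
        samples = []
        for r in df.itertuples():
            hemi = getattr(r, "hemisphere", None)
            if hemi is None or (isinstance(hemi, float) and np.isnan(hemi)) or hemi == "":
                hemi = None
            samples.append(
                SubjectSample(
                    subject_id=str(r.subject_id),
                    birth_year=float(r.birth_year),
                    collection_year=float(r.collection_year),
                    population=str(r.population),
                    delta14c_permil=float(r.delta14c_permil),
                    meas_sd_permil=float(getattr(r, "meas_sd_permil", 0.0)),
                    hemisphere=hemi,
                )
            )
        return cls(samples, record, scenario=scenario, **kw)

    # -- probability pieces in sampling coordinates -------------------

    def _predict_sampled(self, theta: np.ndarray) -> np.ndarray:
        """Predictions for a batch of sampling-coordinate points.

        ``theta`` is (W, ndim); returns (W, n_samples).
        """
        scen = self.scenario
        if scen == "A":
            return self.solver.final_const(np.exp(theta[:, 0]))
        if scen == "LIN":
            return self.solver.final_lin(np.exp(theta[:, 0]), np.exp(theta[:, 1]))
        # 2POP: theta = (log beta, f, sigma)
        return self.solver.final_2pop(np.exp(theta[:, 0]), theta[:, 1])

    def _loglike_sampled(self, theta: np.ndarray) -> float:
        return float(self._logpost_vec(np.asarray(theta)[None, :])[0])

    def _logpost_sampled(self, theta: np.ndarray) -> float:
        return self._loglike_sampled(theta)

    def _logpost_vec(self, theta: np.ndarray) -> np.ndarray:
        """Vectorised log posterior over walkers (the emcee hot path)."""
        theta = np.atleast_2d(theta)
        ok = np.all((theta >= self._lo) & (theta <= self._hi), axis=1)
        ok &= theta[:, -1] > 0.0  # σ = 0 boundary: zero-likelihood state
        out = np.full(theta.shape[0], -np.inf)
        if not np.any(ok):
            return out
        sub = theta[ok]
        pred = self._predict_sampled(sub)
        sigma = sub[:, -1]
        resid = (self._obs - pred) / sigma[:, None]
        n = len(self.samples)
        out[ok] = -0.5 * np.sum(resid**2, axis=1) - n * (np.log(sigma) + 0.5 * _LOG_2PI)
        return out

    def loglike(self, params: ScenarioParams) -> float:
        """Gaussian log-likelihood at natural-unit parameters."""
        if params.sigma <= 0:
            return -np.inf
        return self._loglike_sampled(params.to_sampled())

    def predict(self, params: ScenarioParams) -> np.ndarray:
        return self.solver.predict(params)

    def sample_prior(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n points from the prior in sampling coordinates."""
        return rng.uniform(self._lo, self._hi, size=(n, self.ndim))

    # -- fitting ------------------------------------------------------

    def fit(
        self,
        seed: int,
        *,
        n_walkers: Optional[int] = None,
        n_burn: int = N_BURN,
        n_keep: int = N_KEEP,
        progress: bool = False,
        compute_rhat: bool = True,
    ) -> "TurnoverResults":
        """Run the ensemble sampler and return a results object."""
        if n_walkers is None:
            n_walkers = WALKERS_PER_PARAM * self.ndim
        rng = np.random.default_rng(seed)
        p0 = self.sample_prior(rng, n_walkers)
        # keep σ off the zero boundary for the initial ensemble
        p0[:, -1] = np.maximum(p0[:, -1], 1e-3)

        sampler = emcee.EnsembleSampler(
            n_walkers, self.ndim, self._logpost_vec, vectorize=True
        )
        sampler.random_state = np.random.RandomState(
            rng.integers(0, 2**32 - 1)
        ).get_state()
        state = sampler.run_mcmc(p0, n_burn + n_keep, progress=progress)

        chain = sampler.get_chain(discard=n_burn)  # (steps, walkers, dim)
        chain = np.moveaxis(chain, 0, 1)  # (walkers, steps, dim)
        natural = np.empty_like(chain)
        for j, name in enumerate(self.param_class.sampled_names):
            col = chain[..., j]
            natural[..., j] = np.exp(col) if name.startswith("log_") else col

        accept = float(np.mean(sampler.acceptance_fraction))
        max_rhat = np.nan
        if compute_rhat:
            max_rhat = _split_rhat(chain)
        stuck = accept < MIN_ACCEPTANCE
        if stuck:
            warnings.warn(
                f"{self.scenario}: ensemble acceptance {accept:.3f} < {MIN_ACCEPTANCE}; "
                "chains returned but should not be trusted",
                RuntimeWarning,
            )
        elif compute_rhat and max_rhat > RHAT_WARN:
            warnings.warn(
                f"{self.scenario}: max split-R-hat {max_rhat:.3f} > {RHAT_WARN}",
                RuntimeWarning,
            )

        chains = PosteriorChains(
            scenario=self.scenario,
            param_names=tuple(self.param_class.param_names),
            draws=natural,
            n_burn=n_burn,
            n_keep=n_keep,
            seed=seed,
            acceptance_fraction=accept,
            max_rhat=max_rhat,
            stuck=stuck,
        )
        return TurnoverResults(model=self, chains=chains)


@dataclass
class TurnoverResults:
    """Posterior of one scenario fitted to one cohort."""

    model: TurnoverModel
    chains: PosteriorChains

    def __post_init__(self) -> None:
        self._summary = summarize(self.chains)

    # -- estimates ----------------------------------------------------

    @property
    def params(self) -> ScenarioParams:
        """Posterior-median parameters in natural units."""
        med = self._summary.table["median"]
        return self.model.param_class(**{k: float(med[k]) for k in self.chains.param_names})

    @property
    def scenario(self) -> str:
        return self.chains.scenario

    def summary(self, extra: bool = True) -> PosteriorSummary:
        """Median and 16/84 bounds; 2POP adds the derived f·β row."""
        table = self._summary.table.copy()
        if extra and self.scenario == "2POP":
            _, s = population_turnover(self.chains)
            table = pd.concat([table, s.table])
        table.attrs["scenario"] = self.scenario
        table.attrs["acceptance_fraction"] = self.chains.acceptance_fraction
        table.attrs["max_rhat"] = self.chains.max_rhat
        return PosteriorSummary(table)

    def population_turnover(self):
        """Per-draw f·β and its summary (2POP only)."""
        return population_turnover(self.chains)

    def posterior_probability(self, predicate) -> float:
        """Posterior probability of a predicate on natural-unit draws.

        ``predicate`` receives a dict of parameter-name -> draws array.
        """
        flat = self.chains.flat()
        cols = {n: flat[:, i] for i, n in enumerate(self.chains.param_names)}
        return float(np.mean(predicate(cols)))

    def predict(self) -> np.ndarray:
        """Predictions at the posterior-median parameters."""
        return self.model.predict(self.params)

    def pointwise_loglik(self, thin: int = 1):
        from .loo import pointwise_loglik

        return pointwise_loglik(self.chains, self.model.samples, self.model.record,
                                thin=thin, solver=self.model.solver)


# ---------------------------------------------------------------------------
# per-subject fits (scenario A) and the age correlation
# ---------------------------------------------------------------------------


def fit_individual_rates(
    samples: Sequence[SubjectSample],
    record: AtmosphericRecord,
    seed: int,
    *,
    fix_sigma: Optional[float] = None,
    n_walkers: Optional[int] = None,
    n_burn: int = N_BURN,
    n_keep: int = N_KEEP,
):
    """Scenario-A fit per subject plus the age/turnover correlation.

    Bilateral measurements of one subject are averaged into a single
    value before fitting.  σ is co-estimated per subject by default
    (weakly identified at n = 1 but the posterior median is defined);
    pass ``fix_sigma`` to pin it, e.g. to the AMS uncertainty.

    Returns ``(table, r, p)`` where ``table`` has one row per subject
    (age, beta_hat and its 16/84 bounds) and r, p are the Pearson
    correlation of age at collection with β̂ and its two-sided t-test
    p-value.  With fewer than 3 subjects or a degenerate spread the
    correlation is flagged as NaN.
    """
    # average bilateral duplicates
    by_subject: dict[str, list[SubjectSample]] = {}
    for s in samples:
        by_subject.setdefault(s.subject_id, []).append(s)

    rows = []
    root = np.random.SeedSequence(seed)
    for (sid, group), child in zip(sorted(by_subject.items()), root.spawn(len(by_subject))):
        first = group[0]
        mean_c14 = float(np.mean([g.delta14c_permil for g in group]))
        merged = SubjectSample(
            subject_id=sid,
            birth_year=first.birth_year,
            collection_year=first.collection_year,
            population=first.population,
            delta14c_permil=mean_c14,
            meas_sd_permil=float(np.mean([g.meas_sd_permil for g in group])),
        )
        model = _single_subject_model(merged, record, fix_sigma)
        res = model.fit(
            seed=int(child.generate_state(1)[0] % (2**31)),
            n_walkers=n_walkers,
            n_burn=n_burn,
            n_keep=n_keep,
            compute_rhat=False,
        )
        s = summarize(res.chains).table.loc["beta"]
        rows.append(
            {
                "subject_id": sid,
                "age": merged.age_at_collection,
                "beta_hat": float(s["median"]),
                "beta_lower": float(s["lower_1sig"]),
                "beta_upper": float(s["upper_1sig"]),
                "n_measurements": len(group),
            }
        )
    table = pd.DataFrame(rows).set_index("subject_id")

    r = p = np.nan
    if len(table) >= 3:
        ages = table["age"].to_numpy()
        betas = table["beta_hat"].to_numpy()
        if np.ptp(ages) > 0 and np.ptp(betas) > 1e-12 * max(1.0, np.abs(betas).max()):
            r, p = stats.pearsonr(ages, betas)
    return table, float(r), float(p)


def _single_subject_model(sample, record, fix_sigma):
    model = TurnoverModel([sample], record, scenario="A")
    if fix_sigma is not None:
        lo, hi = model.param_class.sampled_bounds()
        lo = lo.copy()
        hi = hi.copy()
        lo[-1] = fix_sigma - 1e-9
        hi[-1] = fix_sigma + 1e-9
        model._lo, model._hi = lo, hi
    return model
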