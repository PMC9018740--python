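"""Synthetic study inputs.

Everything the pipeline consumes can be generated here with stated
parameters and seeds: a stylised bomb-pulse atmospheric curve, a cohort
of subjects straddling the 1963 atmospheric peak, noisy Δ¹⁴C
measurements produced by the forward model under a chosen scenario,
and multinomial per-neuron lipofuscin counts.

The default cohort mimics a post-mortem birth-dating study design:
births spread over
1930–1980, post-mortem collection in 2015, one neuronal measurement per
subject, plus one mid-cohort subject measured bilaterally (two
measurements with independent noise).  The default generating scenario
is 2POP with a renewing fraction of 0.29 at rate 0.1 /year and noise
SD 10 ‰.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .atmosphere import AtmosphericRecord
from .lipofuscin import LipofuscinCounts
from .samples import SubjectSample
from .scenarios import Scenario2POPParams, ScenarioParams, params_to_dict
from .forward import predict_cohort

__all__ = [
    "BombCurveSpec",
    "make_bomb_curve",
    "SimSpec",
    "simulate_measurements",
    "simulate_lipofuscin",
    "default_sim_spec",
]


@dataclass(frozen=True)
class BombCurveSpec:
    """Stylised bomb-pulse curve: flat baseline, logistic rise to the
    1963 peak, exponential relaxation back toward baseline.

    Units: ‰ for values, decimal calendar years for times.
    """

    baseline: float = -5.0
    rise_start: float = 1955.0
    peak_year: float = 1963.5
    peak: float = 800.0
    decay_tau: float = 16.0
    end_year: float = 2025.0
    start_year: float = 1920.0

    def __post_init__(self) -> None:
        if not (self.start_year < self.rise_start < self.peak_year < self.end_year):
            raise ValueError("need start_year < rise_start < peak_year < end_year")
        if self.peak <= self.baseline:
            raise ValueError("peak must exceed baseline")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")


def make_bomb_curve(spec: BombCurveSpec = BombCurveSpec()) -> AtmosphericRecord:
    """Evaluate the stylised curve on knots at 0.5-year spacing.

    The logistic rise is rescaled so the curve is exactly ``baseline``
    at ``rise_start`` and exactly ``peak`` at ``peak_year`` (both are
    knots when they sit on the 0.5-year lattice); after the peak the
    excess decays as exp(−(t − peak_year)/τ).
    """
    years = np.arange(spec.start_year, spec.end_year + 0.25, 0.5)
    values = np.full_like(years, spec.baseline)

    mid = 0.5 * (spec.rise_start + spec.peak_year)
    width = (spec.peak_year - spec.rise_start) / 10.0

    def sigmoid(t):
        return 1.0 / (1.0 + np.exp(-(t - mid) / width))

    s0, s1 = sigmoid(spec.rise_start), sigmoid(spec.peak_year)
    rising = (years >= spec.rise_start) & (years <= spec.peak_year)
    values[rising] = spec.baseline + (spec.peak - spec.baseline) * (
        (sigmoid(years[rising]) - s0) / (s1 - s0)
    )
    after = years > spec.peak_year
    values[after] = spec.baseline + (spec.peak - spec.baseline) * np.exp(
        -(years[after] - spec.peak_year) / spec.decay_tau
    )
    return AtmosphericRecord(years=years, values=values)


@dataclass(frozen=True)
class SimSpec:
    """Design of a synthetic Δ¹⁴C cohort.

    Births are evenly spaced over ``birth_range`` so the cohort always
    straddles the bomb peak; noise and the bilateral duplicate are the
    only seed-dependent pieces.
    """

    params: ScenarioParams
    n_subjects: int = 12
    birth_range: tuple = (1930.0, 1980.0)
    collection_year: float = 2015.0
    seed: int = 0
    population: str = "neuronal"
    bilateral_subject: Optional[int] = None  # index; default: middle subject
    include_bilateral: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.collection_year > self.birth_range[1]:
            raise ValueError("collection year must follow all birth years")
        if self.params.sigma < 0:
            raise ValueError("sigma must be >= 0")


def default_sim_spec(seed: int = 0, **kw) -> SimSpec:
    """Study-scale default conditions: 2POP, f = 0.29, β = 0.1 /year, σ = 10 ‰."""
    params = kw.pop("params", Scenario2POPParams(beta=0.1, f=0.29, sigma=10.0))
    return SimSpec(params=params, seed=seed, **kw)


def simulate_measurements(
    spec: SimSpec, record: AtmosphericRecord
) -> tuple[list[SubjectSample], dict]:
    """Forward-simulate noisy Δ¹⁴C measurements for a cohort.

    Each measurement is the forward-model prediction at collection plus
    Normal(0, σ) noise.  Returns (samples, truth) where ``truth`` is
    the ground-truth sidecar (scenario, parameters, noise-free
    predictions, seed) that should be persisted next to the data.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_subjects == 1:
        births = np.array([np.mean(spec.birth_range)])
    else:
        births = np.linspace(spec.birth_range[0], spec.birth_range[1], spec.n_subjects)

    base = [
        SubjectSample(
            subject_id=f"S{i + 1:02d}",
            birth_year=float(b),
            collection_year=spec.collection_year,
            population=spec.population,
            delta14c_permil=0.0,
            meas_sd_permil=0.0,
        )
        for i, b in enumerate(births)
    ]
    plan: list[tuple[SubjectSample, Optional[str]]] = [(s, None) for s in base]
    if spec.include_bilateral and spec.n_subjects >= 1:
        idx = spec.bilateral_subject
        if idx is None:
            idx = spec.n_subjects // 2
        donor = base[idx]
        plan[idx] = (donor, "left")
        plan.append((donor, "right"))

    skeleton = [s for s, _ in plan]
    clean = predict_cohort(spec.params, skeleton, record)
    noise = rng.normal(0.0, spec.params.sigma, size=len(plan))

    samples = [
        SubjectSample(
            subject_id=s.subject_id,
            birth_year=s.birth_year,
            collection_year=s.collection_year,
            population=s.population,
            delta14c_permil=float(clean[i] + noise[i]),
            meas_sd_permil=float(spec.params.sigma),
            hemisphere=hemi,
        )
        for i, (s, hemi) in enumerate(plan)
    ]
    truth = {
        "scenario": spec.params.scenario,
        "params": params_to_dict(spec.params),
        "seed": spec.seed,
        "collection_year": spec.collection_year,
        "noise_free_predictions": {
            f"{s.subject_id}:{hemi or ''}": float(clean[i])
            for i, (s, hemi) in enumerate(plan)
        },
    }
    return samples, truth


def write_truth_json(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# lipofuscin counts
# ---------------------------------------------------------------------------


def simulate_lipofuscin(
    n_subjects: int,
    n_neurons: int,
    bin_probs,
    seed: int,
) -> list[LipofuscinCounts]:
    """Multinomial per-neuron granule counts over the three bins.

    ``bin_probs`` are the probabilities of the (0, 1–3, >3) bins; a
    neuron in the low bin gets a count uniform on {1..3}, one in the
    abundant bin uniform on {4..12}.
    """
    p = np.asarray(bin_probs, dtype=float)
    if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("bin_probs must be three non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        bins = rng.choice(3, size=n_neurons, p=p)
        counts = np.zeros(n_neurons, dtype=int)
        low = bins == 1
        high = bins == 2
        counts[low] = rng.integers(1, 4, size=int(low.sum()))
        counts[high] = rng.integers(4, 13, size=int(high.sum()))
        subjects.append(LipofuscinCounts(subject_id=f"L{i + 1}", counts=counts))
    return subjects
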