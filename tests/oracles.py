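"""Independent oracles used by the test suite.

Everything here is deliberately naive and separate from the package
implementation: a cell-by-cell Monte-Carlo simulation of the population
balance (each cell is replaced at its hazard and picks up the current
lagged atmospheric value), a hand-rolled tie-corrected Kruskal–Wallis
statistic, and an exact grid-refit leave-one-out computation for the
two-parameter constant-rate model.
"""

import numpy as np

from c14turnover import Scenario2POPParams
from c14turnover.scenarios import RATE_MAX, RATE_MIN


def mc_cohort_mean_label(params, sample, record, n_cells=20000, dt=0.02, seed=0):
    """Monte-Carlo mean Δ¹⁴C label of a replaced-at-hazard cohort.

    Simulates the population balance directly: every cell carries the
    lagged atmospheric value of its own birth moment, and in each step
    of length dt is replaced with probability 1 − e^{−β·dt} (midpoint
    hazard).  Returns (mean, sd, n_cells).
    """
    rng = np.random.default_rng(seed)
    T = sample.age_at_collection
    steps = int(np.ceil(T / dt))
    h = T / steps
    labels = np.full(n_cells, record.lagged_lookup(sample.birth_year))

    if isinstance(params, Scenario2POPParams):
        renewing = rng.random(n_cells) < params.f
    else:
        renewing = np.ones(n_cells, dtype=bool)

    for k in range(steps):
        t_mid = (k + 0.5) * h
        beta = params.rate(t_mid)
        p = -np.expm1(-beta * h)
        replaced = renewing & (rng.random(n_cells) < p)
        if replaced.any():
            labels[replaced] = record.lagged_lookup(sample.birth_year + t_mid)
    return float(labels.mean()), float(labels.std(ddof=1)), n_cells


def mc_cohort_mean_age(beta, t, n_cells=20000, dt=0.02, seed=0):
    """Monte-Carlo mean cell age under constant-hazard replacement."""
    rng = np.random.default_rng(seed)
    steps = int(np.ceil(t / dt))
    h = t / steps
    birth = np.zeros(n_cells)
    p = -np.expm1(-beta * h)
    for k in range(steps):
        replaced = rng.random(n_cells) < p
        birth[replaced] = (k + 0.5) * h
    ages = t - birth
    return float(ages.mean()), float(ages.std(ddof=1)), n_cells


def rank_with_ties(values):
    """Average ranks (1-based), computed by brute force."""
    values = np.asarray(values, dtype=float)
    ranks = np.empty(values.size)
    for i, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def kruskal_wallis_hand(groups):
    """Tie-corrected Kruskal–Wallis H from the textbook rank formula."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    N = pooled.size
    ranks = rank_with_ties(pooled)
    H = 0.0
    start = 0
    for n_j in sizes:
        R_j = ranks[start : start + n_j].sum()
        H += R_j**2 / n_j
        start += n_j
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    corr = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    if corr > 0:
        H /= corr
    return H


def grid_posterior_a(solver, observations, n_beta=160, n_sigma=160, sigma_max=100.0):
    """Dense-grid posterior for the constant-rate scenario.

    Returns (log_beta grid, sigma grid, loglik matrix (G_b, G_s, n)),
    using the same uniform-in-(log β, σ) prior as the sampler, so the
    posterior over the grid is just the normalised likelihood.
    """
    log_beta = np.linspace(np.log(RATE_MIN), np.log(RATE_MAX), n_beta)
    sigma = np.linspace(sigma_max / n_sigma, sigma_max, n_sigma)
    pred = solver.final_const(np.exp(log_beta))  # (G_b, n)
    obs = np.asarray(observations)
    resid = obs[None, :] - pred  # (G_b, n)
    z2 = (resid[:, None, :] / sigma[None, :, None]) ** 2
    ll = -0.5 * z2 - np.log(sigma)[None, :, None] - 0.5 * np.log(2 * np.pi)
    return log_beta, sigma, ll


def exact_loo_elpd_from_grid(ll):
    """Exact leave-one-out elpd by grid 'refits'.

    ll is (G_b, G_s, n) pointwise log-likelihood on a prior-uniform
    grid.  For each observation i the LOO posterior is the normalised
    product of the other likelihoods, and
    lpd_i = log Σ_g p(y_i|θ_g)·w_g^{(−i)}.
    """
    from scipy.special import logsumexp

    G = ll.shape[0] * ll.shape[1]
    flat = ll.reshape(G, ll.shape[2])
    total = flat.sum(axis=1)  # log-lik of all obs per grid node
    lpd = np.empty(ll.shape[2])
    for i in range(ll.shape[2]):
        log_post_wo_i = total - flat[:, i]
        log_norm = logsumexp(log_post_wo_i)
        lpd[i] = logsumexp(log_post_wo_i - log_norm + flat[:, i])
    return float(lpd.sum()), lpd
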