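"""Lipofuscin granule statistics.

Lipofuscin is the autofluorescent "age pigment" that accumulates in
postmitotic cells; a neuron devoid of it is substantially younger than
the individual.  Per-neuron granule counts are trichotomised into
absence (0 granules), low deposition (1–3) and abundant deposition
(>3); per-subject bin proportions are summarised as mean ± SEM and the
three bins are compared with the tie-corrected Kruskal–Wallis rank test
followed by a Tukey-style (Nemenyi) post hoc on rank sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BIN_LABELS",
    "LipofuscinCounts",
    "trichotomize",
    "group_summary",
    "kruskal_wallis",
    "posthoc_pairwise",
    "read_counts_csv",
    "analyze_counts",
]

BIN_LABELS = ("0", "1-3", ">3")


@dataclass(frozen=True)
class LipofuscinCounts:
    """Granule counts per neuron for one subject."""

    subject_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.size == 0:
            raise ValueError(f"{self.subject_id}: no neurons counted")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            c = c.astype(float)
            if np.any(c < 0) or np.any(c != np.round(c)):
                raise ValueError(f"{self.subject_id}: counts must be non-negative integers")
        object.__setattr__(self, "counts", np.asarray(c, dtype=int))

    @property
    def n_neurons(self) -> int:
        return self.counts.size


def trichotomize(subjects: Sequence[LipofuscinCounts]) -> pd.DataFrame:
    """Per-subject proportions in the bins {0}, {1–3}, {>3}.

    Returns a frame indexed by subject with columns ``BIN_LABELS`` plus
    ``n_neurons``; the three proportions sum to 1 per subject.
    """
    rows = {}
    for s in subjects:
        c = s.counts
        n = c.size
        rows[s.subject_id] = {
            "0": np.sum(c == 0) / n,
            "1-3": np.sum((c >= 1) & (c <= 3)) / n,
            ">3": np.sum(c > 3) / n,
            "n_neurons": n,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def group_summary(props: pd.DataFrame) -> pd.DataFrame:
    """Across-subject mean ± SEM per bin, with a normal 95% interval.

    Needs at least two subjects for the SEM; with one subject the SEM
    and interval are NaN (flagged, not an error).
    """
    n = len(props)
    if n == 0:
        raise ValueError("no subjects")
    out = {}
    for b in BIN_LABELS:
        vals = props[b].to_numpy(float)
        mean = float(np.mean(vals))
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        out[b] = {
            "mean": mean,
            "sem": sem,
            "ci95_lower": mean - 1.96 * sem if n >= 2 else np.nan,
            "ci95_upper": mean + 1.96 * sem if n >= 2 else np.nan,
            "n_subjects": n,
        }
    return pd.DataFrame.from_dict(out, orient="index")


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p-value.

    ``groups`` are the per-subject proportion vectors, one per bin.
    Returns (H, df, p); all observations tied across all groups gives
    H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    H, p = stats.kruskal(*arrays)
    return float(H), df, float(p)


def posthoc_pairwise(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] = BIN_LABELS,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Nemenyi (Tukey-q on rank sums) pairwise comparisons.

    Gatekept on the omnibus Kruskal–Wallis being significant at
    ``alpha``: if it is not, an empty frame with a ``reason`` attr is
    returned.  For each pair the studentized-range statistic

        q = √2 · |R̄_i − R̄_j| / √(N(N+1)/12 · (1/n_i + 1/n_j))

    is referred to the studentized range distribution with the number
    of groups and infinite degrees of freedom; decisions are flagged at
    α = 0.05 and α = 0.001.
    """
    H, df, p = kruskal_wallis(groups)
    if p >= alpha:
        out = pd.DataFrame(
            columns=["group_a", "group_b", "q", "p", "sig_0.05", "sig_0.001"]
        )
        out.attrs["reason"] = (
            f"omnibus Kruskal-Wallis not significant (H={H:.4g}, p={p:.4g})"
        )
        return out

    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    sizes = np.array([a.size for a in arrays])
    N = int(sizes.sum())
    ranks = stats.rankdata(np.concatenate(arrays))
    mean_ranks = []
    start = 0
    for n_i in sizes:
        mean_ranks.append(ranks[start : start + n_i].mean())
        start += n_i

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(N * (N + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = np.sqrt(2.0) * abs(mean_ranks[i] - mean_ranks[j]) / se
            p_pair = float(stats.studentized_range.sf(q, k, np.inf))
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "q": float(q),
                    "p": p_pair,
                    "sig_0.05": p_pair < 0.05,
                    "sig_0.001": p_pair < 0.001,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["reason"] = ""
    return out


def read_counts_csv(path) -> list[LipofuscinCounts]:
    """Read a ``subject_id,neuron_id,granules`` table into per-subject counts."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = {"subject_id", "neuron_id", "granules"} - set(df.columns)
    if missing:
        raise ValueError(f"counts CSV missing columns: {sorted(missing)}")
    return [
        LipofuscinCounts(subject_id=sid, counts=g["granules"].to_numpy())
        for sid, g in df.groupby("subject_id", sort=True)
    ]


def analyze_counts(subjects: Sequence[LipofuscinCounts]) -> dict:
    """Full lipofuscin analysis: proportions, summary, KW test, post hoc."""
    props = trichotomize(subjects)
    summary = group_summary(props)
    groups = [props[b].to_numpy(float) for b in BIN_LABELS]
    H, df, p = kruskal_wallis(groups)
    posthoc = posthoc_pairwise(groups)
    return {
        "proportions": props,
        "summary": summary,
        "kruskal_wallis": {"H": H, "df": df, "p": p},
        "posthoc": posthoc,
    }
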