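"""Discrimination preference indices and their group statistics.

Novel-object recognition and Y-maze trials both score recognition memory as

    index = (t_novel - t_familiar) / (t_novel + t_familiar)

in [-1, 1], with 0 meaning no discrimination.  Group comparison follows the
classic protected route: a one-way ANOVA across all groups, then Fisher's
LSD pairwise t-tests on the pooled error variance when the omnibus test is
significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "preference_index",
    "read_behavior",
    "trial_indices",
    "BehaviorStats",
    "group_anova_lsd",
]

BEHAVIOR_COLUMNS = ("animal", "group", "paradigm", "t_novel", "t_familiar")


def preference_index(t_novel: float, t_familiar: float) -> float:
    """(novel - familiar) / (novel + familiar) exploration-time index."""
    if t_novel < 0 or t_familiar < 0:
        raise ValueError("exploration times must be non-negative")
    total = t_novel + t_familiar
    if total == 0:
        raise ValueError("total exploration time is zero; index undefined")
    return (t_novel - t_familiar) / total


def read_behavior(path) -> pd.DataFrame:
    """Read a trial table: animal, group, paradigm, t_novel, t_familiar."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in BEHAVIOR_COLUMNS[:3]})
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("t_novel", "t_familiar"):
        df[col] = pd.to_numeric(df[col])
    return df


def trial_indices(trials: pd.DataFrame) -> pd.DataFrame:
    """Add an ``index`` column; trials with zero total time are dropped.

    Dropped trials are listed in ``result.attrs['excluded_trials']``.
    """
    total = trials["t_novel"] + trials["t_familiar"]
    if (trials[["t_novel", "t_familiar"]] < 0).any().any():
        raise ValueError("exploration times must be non-negative")
    keep = total > 0
    out = trials.loc[keep].copy()
    out["index"] = (out["t_novel"] - out["t_familiar"]) / (
        out["t_novel"] + out["t_familiar"]
    )
    out.attrs["excluded_trials"] = trials.loc[~keep, "animal"].tolist()
    return out


@dataclass
class BehaviorStats:
    """One-way ANOVA plus Fisher-LSD pairwise p-values on group indices."""

    groups: list[str]
    n: dict[str, int]
    means: dict[str, float]
    sems: dict[str, float]
    f: float
    df_between: int
    df_within: int
    p_anova: float
    mse: float
    lsd_p: pd.DataFrame  # pairwise p-values; NaN when LSD not performed

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.n,
                "mean": self.means,
                "sem": self.sems,
            }
        ).loc[self.groups]


def group_anova_lsd(
    values: pd.Series | np.ndarray,
    groups: pd.Series | list[str],
    protected: bool = True,
    alpha: float = 0.05,
) -> BehaviorStats:
    """One-way ANOVA with Fisher's LSD post hoc tests.

    LSD p-values use the pooled mean squared error with N - k degrees of
    freedom and are unadjusted.  With ``protected=True`` (Fisher's protected
    procedure) the pairwise matrix is filled only when the omnibus ANOVA
    p-value is at most ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    labels = pd.Series(groups, dtype=str).reset_index(drop=True)
    if len(values) != len(labels):
        raise ValueError("values and groups differ in length")
    order = list(dict.fromkeys(labels))
    if len(order) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    samples = {g: values[(labels == g).to_numpy()] for g in order}
    for g, x in samples.items():
        if len(x) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    k = len(order)
    n_total = len(values)
    df_between, df_within = k - 1, n_total - k
    mse = sum((len(x) - 1) * np.var(x, ddof=1) for x in samples.values()) / df_within
    if mse == 0:
        raise ValueError("zero within-group variance; F undefined")
    f, p = stats.f_oneway(*samples.values())

    lsd = pd.DataFrame(np.nan, index=order, columns=order, dtype=float)
    if not protected or p <= alpha:
        for i, a in enumerate(order):
            for b in order[i + 1:]:
                diff = samples[a].mean() - samples[b].mean()
                se = np.sqrt(mse * (1 / len(samples[a]) + 1 / len(samples[b])))
                t = diff / se
                p_ab = 2.0 * stats.t.sf(abs(t), df_within)
                lsd.loc[a, b] = lsd.loc[b, a] = p_ab
    np.fill_diagonal(lsd.to_numpy(), np.nan)

    return BehaviorStats(
        groups=order,
        n={g: len(x) for g, x in samples.items()},
        means={g: float(x.mean()) for g, x in samples.items()},
        sems={g: float(np.std(x, ddof=1) / np.sqrt(len(x))) for g, x in samples.items()},
        f=float(f),
        df_between=df_between,
        df_within=df_within,
        p_anova=float(p),
        mse=float(mse),
        lsd_p=lsd,
    )
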