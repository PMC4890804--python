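"""Z-score / Z-ratio differential expression with a five-criterion filter.

The chain implemented here is the classic intensity-ratio-free microarray
analysis: per-array standardization of log intensities to Z-scores, a
Z-ratio statistic per probe for each group-vs-group comparison, and a
conjunction of five selection criteria:

1. two-sided z-test p-value of the Z-ratio <= ``p_z_max``,
2. ``|Z-ratio| >= z_ratio_min``,
3. Benjamini-Hochberg FDR q <= ``fdr_max``,
4. average Z-score over all samples of the compared groups not negative
   (an expression filter: the probe is at or above the array average), and
5. one-way ANOVA p across *all* design groups <= ``p_anova_max``.

All statistics are vectorized over probes; probes with missing values in a
compared group are excluded from that comparison and listed in the result's
``attrs['excluded_probes']``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleDesign

__all__ = [
    "ZScoreMatrix",
    "SelectionThresholds",
    "log_transform",
    "zscore_normalize",
    "zratio",
    "fold_change",
    "ztest_pvalues",
    "bh_fdr",
    "anova_pvalues",
    "average_zscore",
    "select_significant",
    "compare",
]


@dataclass
class ZScoreMatrix:
    """Per-sample standardized log expression (column mean 0, sd 1)."""

    data: pd.DataFrame
    log_base: float = 10.0

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SelectionThresholds:
    """The five selection-criterion cutoffs."""

    p_z_max: float = 0.05
    z_ratio_min: float = 1.5
    fdr_max: float = 0.30
    require_nonneg_avg_z: bool = True
    p_anova_max: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_z_max", "fdr_max", "p_anova_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.z_ratio_min < 0:
            raise ValueError("z_ratio_min must be non-negative")


def log_transform(
    matrix: ExpressionMatrix, base: float = 10.0, floor: float = 1.0
) -> ExpressionMatrix:
    """Log-transform a raw intensity matrix: ``log_base(max(x, floor))``.

    The floor guards zero intensities; missing values stay missing.
    """
    if matrix.scale != "raw":
        raise ValueError("log_transform expects a raw-scale matrix")
    if base <= 1:
        raise ValueError(f"log base must exceed 1, got {base}")
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    vals = matrix.data.to_numpy(dtype=float)
    out = np.log(np.maximum(vals, floor)) / np.log(base)
    out[~np.isfinite(vals)] = np.nan
    frame = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(frame, scale="log", log_base=base)


def zscore_normalize(matrix: ExpressionMatrix) -> ZScoreMatrix:
    """Standardize each sample column to mean 0, sd 1 (denominator n-1).

    Mean and sd are computed over the non-missing probes of each column, so
    any per-array affine distortion of the log intensities (scanner scale or
    offset) is removed exactly.
    """
    if matrix.scale != "log":
        raise ValueError("zscore_normalize expects a log-scale matrix")
    data = matrix.data
    z = {}
    for col in data.columns:
        x = data[col]
        obs = x.dropna()
        if len(obs) < 2:
            raise ValueError(f"sample {col!r} has fewer than 2 non-missing probes")
        sd = obs.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"sample {col!r} has zero variance")
        z[col] = (x - obs.mean()) / sd
    frame = pd.DataFrame(z, index=data.index)
    return ZScoreMatrix(frame, log_base=matrix.log_base or 10.0)


def _complete_probes(z: pd.DataFrame, samples: list[str]) -> pd.Series:
    return z[samples].notna().all(axis=1)


def zratio(
    z: ZScoreMatrix,
    design: SampleDesign,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-probe Z-ratio for group A vs group B.

    ``delta_z`` is the difference of group-mean Z-scores; the Z-ratio divides
    it by the standard deviation (n-1) of ``delta_z`` over all probes in the
    comparison, so the Z-ratio vector has sd exactly 1 across probes.

    Probes with a missing Z-score in either compared group are excluded and
    reported in ``result.attrs['excluded_probes']``.
    """
    design.require_groups(group_a, group_b, min_size=2)
    samples_a = design.samples_in(group_a)
    samples_b = design.samples_in(group_b)
    keep = _complete_probes(z.data, samples_a + samples_b)
    excluded = z.data.index[~keep].tolist()
    sub = z.data.loc[keep]
    if len(sub) < 2:
        raise ValueError("fewer than 2 probes with complete data in comparison")
    mean_a = sub[samples_a].mean(axis=1)
    mean_b = sub[samples_b].mean(axis=1)
    delta = mean_a - mean_b
    denom = delta.std(ddof=1)
    if denom == 0:
        if (delta == 0).all():
            # identical group means everywhere: no differential signal at all
            ratio = delta.copy()
        else:
            raise ValueError(
                "delta Z is a nonzero constant across probes; Z-ratio undefined"
            )
    else:
        ratio = delta / denom
    result = pd.DataFrame(
        {
            "mean_z_a": mean_a,
            "mean_z_b": mean_b,
            "delta_z": delta,
            "z_ratio": ratio,
            "avg_z": sub[samples_a + samples_b].mean(axis=1),
        }
    )
    result.attrs["excluded_probes"] = excluded
    result.attrs["comparison"] = (group_a, group_b)
    return result


def fold_change(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    group_a: str,
    group_b: str,
) -> pd.Series:
    """Signed fold change of raw group-mean intensities (A over B).

    The signed-ratio convention reports a ratio ``r >= 1`` as ``+r`` and
    ``r < 1`` as ``-1/r``, so a halving is -2.0 and no change is +1.0.
    A zero denominator mean yields a missing value.
    """
    if matrix.scale != "raw":
        raise ValueError("fold_change expects a raw-scale matrix")
    design.require_groups(group_a, group_b, min_size=1)
    mean_a = matrix.data[design.samples_in(group_a)].mean(axis=1)
    mean_b = matrix.data[design.samples_in(group_b)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = mean_a / mean_b
    r[mean_b == 0] = np.nan
    signed = np.where(r >= 1, r, -1.0 / r)
    return pd.Series(signed, index=matrix.data.index, name="fold_change")


def ztest_pvalues(z_ratios: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Two-sided normal p-values treating Z-ratios as standard normal deviates."""
    arr = np.asarray(z_ratios, dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(arr))
    if isinstance(z_ratios, pd.Series):
        return pd.Series(p, index=z_ratios.index, name="p_z")
    return p


def bh_fdr(pvalues: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1.

    Missing p-values propagate as missing and do not enter the ranking.
    """
    arr = np.asarray(pvalues, dtype=float)
    mask = np.isfinite(arr)
    if mask.any():
        if arr[mask].min() < 0 or arr[mask].max() > 1:
            raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(arr, np.nan)
    if mask.any():
        q[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(q, index=pvalues.index, name="q")
    return q


def anova_pvalues(z: ZScoreMatrix, design: SampleDesign) -> pd.DataFrame:
    """Per-probe one-way fixed-effects ANOVA across *all* design groups.

    Returns a frame with columns ``F`` and ``p_anova`` indexed by probe.
    Probes with any missing value are returned as missing.
    """
    if len(design.groups) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    design.require_groups(*design.groups, min_size=2)
    all_samples = [s for g in design.groups for s in design.samples_in(g)]
    keep = _complete_probes(z.data, all_samples)
    sub = z.data.loc[keep]
    arrays = [sub[design.samples_in(g)].to_numpy(dtype=float) for g in design.groups]
    f, p = stats.f_oneway(*arrays, axis=1)
    out = pd.DataFrame(
        {"F": np.nan, "p_anova": np.nan}, index=z.data.index, dtype=float
    )
    out.loc[keep, "F"] = f
    out.loc[keep, "p_anova"] = p
    return out


def average_zscore(
    z: ZScoreMatrix, design: SampleDesign, group_a: str, group_b: str
) -> pd.Series:
    """Mean Z-score per probe over all samples of the two compared groups."""
    samples = design.samples_in(group_a) + design.samples_in(group_b)
    return z.data[samples].mean(axis=1).rename("avg_z")


_CRITERION_FIELDS = ("p_z", "z_ratio", "q", "avg_z", "p_anova")


def select_significant(
    result: pd.DataFrame, thresholds: SelectionThresholds | None = None
) -> pd.DataFrame:
    """Apply the five-criterion conjunction; adds ``significant``/``direction``.

    ``direction`` is "up"/"down" by the sign of the Z-ratio for significant
    probes and "none" otherwise.
    """
    thresholds = thresholds or SelectionThresholds()
    missing = [f for f in _CRITERION_FIELDS if f not in result.columns]
    if missing:
        raise ValueError(f"criterion field(s) not populated: {missing}")
    ok = (
        (result["p_z"] <= thresholds.p_z_max)
        & (result["z_ratio"].abs() >= thresholds.z_ratio_min)
        & (result["q"] <= thresholds.fdr_max)
        & (result["p_anova"] <= thresholds.p_anova_max)
    )
    if thresholds.require_nonneg_avg_z:
        ok &= result["avg_z"] >= 0
    for f in _CRITERION_FIELDS:
        ok &= result[f].notna()
    out = result.copy()
    out["significant"] = ok.to_numpy()
    out["direction"] = np.where(
        ~ok, "none", np.where(result["z_ratio"] > 0, "up", "down")
    )
    out.attrs.update(result.attrs)
    return out


def compare(
    z: ZScoreMatrix,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    *,
    raw: ExpressionMatrix | None = None,
    thresholds: SelectionThresholds | None = None,
    anova: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full comparison table for group A vs group B.

    Composes :func:`zratio`, :func:`ztest_pvalues`, :func:`bh_fdr`,
    :func:`anova_pvalues` (recomputed unless a precomputed frame is passed)
    and :func:`select_significant`.  When the raw matrix is supplied, signed
    fold changes are included.
    """
    result = zratio(z, design, group_a, group_b)
    result["p_z"] = ztest_pvalues(result["z_ratio"])
    result["q"] = bh_fdr(result["p_z"])
    if anova is None:
        anova = anova_pvalues(z, design)
    result["p_anova"] = anova.loc[result.index, "p_anova"]
    if raw is not None:
        result["fold_change"] = fold_change(matrix=raw, design=design,
                                            group_a=group_a, group_b=group_b)
    return select_significant(result, thresholds)
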