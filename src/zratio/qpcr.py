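"""Pfaffl relative quantification of qPCR data and array/qPCR comparison.

The Pfaffl model corrects relative expression for amplification efficiency:

    R = E_target ** dCt_target / E_ref ** dCt_ref

with ``dCt = mean Ct (control group) - mean Ct (treated group)`` for each
gene and ``E`` the fold amplification per cycle (2.0 for perfect doubling).
With both efficiencies equal to 2 this reduces exactly to the familiar
``2**(-ddCt)`` method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PfafflResult",
    "pfaffl_ratio",
    "efficiency_from_dilution",
    "signed_fold",
    "read_qpcr",
    "group_fold_change",
    "compare_platforms",
]

QPCR_COLUMNS = ("gene", "sample", "group", "Ct")


@dataclass
class PfafflResult:
    """Efficiency-corrected relative expression of one target gene."""

    gene: str
    e_target: float
    e_ref: float
    dct_target: float
    dct_ref: float
    ratio: float
    fold_change_signed: float
    sem: float
    p_ttest: float
    n_control: int
    n_treated: int


def _check_efficiency(e: float, name: str) -> None:
    if not 1.0 < e <= 2.0:
        raise ValueError(f"{name} must lie in (1, 2], got {e}")


def pfaffl_ratio(
    e_target: float, dct_target: float, e_ref: float, dct_ref: float
) -> float:
    """Efficiency-corrected expression ratio R = E_t^dCt_t / E_r^dCt_r."""
    _check_efficiency(e_target, "e_target")
    _check_efficiency(e_ref, "e_ref")
    return e_target**dct_target / e_ref**dct_ref


def efficiency_from_dilution(slope: float, base: float = 10.0) -> float:
    """Amplification efficiency from a standard-curve slope (Ct vs log input).

    Perfect doubling corresponds to a slope of -1/log10(2) = -3.3219 and
    yields E = 2.0.
    """
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return base ** (-1.0 / slope)


def signed_fold(ratio: float) -> float:
    """Map a positive expression ratio to the signed fold-change convention."""
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    return ratio if ratio >= 1 else -1.0 / ratio


def read_qpcr(path) -> pd.DataFrame:
    """Read a long-format qPCR table: gene, sample, group, Ct (TSV, header)."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in QPCR_COLUMNS[:3]})
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df["Ct"] = pd.to_numeric(df["Ct"])
    return df


def _gene_cts(records: pd.DataFrame, gene: str, group: str) -> pd.Series:
    sel = records[(records["gene"] == gene) & (records["group"] == group)]
    if sel.empty:
        raise ValueError(f"no Ct records for gene {gene!r} in group {group!r}")
    return sel.set_index("sample")["Ct"]


def group_fold_change(
    records: pd.DataFrame,
    target: str,
    reference: str,
    control_group: str,
    treated_group: str,
    e_target: float = 2.0,
    e_ref: float = 2.0,
) -> PfafflResult:
    """Pfaffl fold change of ``target`` (normalized to ``reference``) between
    a treated and a control group.

    dCt is taken as control-group mean Ct minus treated-group mean Ct, so a
    ratio above 1 means up-regulation in the treated group.  Per-sample
    ratios (each sample's Ct against the control-group mean) provide the SEM
    of the treated group and an unpaired two-sided t-test on log ratios.
    Samples lacking a reference-gene Ct are excluded with a warning.
    """
    _check_efficiency(e_target, "e_target")
    _check_efficiency(e_ref, "e_ref")

    per_group: dict[str, pd.DataFrame] = {}
    for group in (control_group, treated_group):
        ct_t = _gene_cts(records, target, group)
        ct_r = _gene_cts(records, reference, group)
        common = ct_t.index.intersection(ct_r.index)
        dropped = ct_t.index.difference(common)
        if len(dropped):
            warnings.warn(
                f"group {group!r}: sample(s) {list(dropped)} lack a "
                f"reference-gene Ct and were excluded"
            )
        if len(common) < 2:
            raise ValueError(f"group {group!r} has < 2 complete samples")
        per_group[group] = pd.DataFrame(
            {"ct_target": ct_t.loc[common], "ct_ref": ct_r.loc[common]}
        )

    ctrl = per_group[control_group]
    trt = per_group[treated_group]
    dct_target = float(ctrl["ct_target"].mean() - trt["ct_target"].mean())
    dct_ref = float(ctrl["ct_ref"].mean() - trt["ct_ref"].mean())
    ratio = pfaffl_ratio(e_target, dct_target, e_ref, dct_ref)

    def per_sample_ratios(frame: pd.DataFrame) -> np.ndarray:
        dct_t = ctrl["ct_target"].mean() - frame["ct_target"].to_numpy()
        dct_r = ctrl["ct_ref"].mean() - frame["ct_ref"].to_numpy()
        return e_target**dct_t / e_ref**dct_r

    ratios_ctrl = per_sample_ratios(ctrl)
    ratios_trt = per_sample_ratios(trt)
    sem = float(np.std(ratios_trt, ddof=1) / math.sqrt(len(ratios_trt)))
    tt = stats.ttest_ind(np.log(ratios_trt), np.log(ratios_ctrl))
    return PfafflResult(
        gene=target,
        e_target=e_target,
        e_ref=e_ref,
        dct_target=dct_target,
        dct_ref=dct_ref,
        ratio=float(ratio),
        fold_change_signed=signed_fold(float(ratio)),
        sem=sem,
        p_ttest=float(tt.pvalue),
        n_control=len(ratios_ctrl),
        n_treated=len(ratios_trt),
    )


def compare_platforms(
    qpcr_fold: float | PfafflResult, array_fold: float
) -> dict[str, float]:
    """Compare a qPCR signed fold change with the array's for the same gene.

    Both values are converted back to plain ratios; the report carries both
    signed folds, their ratio and the absolute log2 difference.
    """
    if isinstance(qpcr_fold, PfafflResult):
        qpcr_fold = qpcr_fold.fold_change_signed
    for name, v in (("qpcr_fold", qpcr_fold), ("array_fold", array_fold)):
        if v == 0 or abs(v) < 1:
            raise ValueError(f"{name} must follow the signed convention (|f|>=1)")
    r_q = qpcr_fold if qpcr_fold > 0 else -1.0 / qpcr_fold
    r_a = array_fold if array_fold > 0 else -1.0 / array_fold
    return {
        "qpcr_fold": float(qpcr_fold),
        "array_fold": float(array_fold),
        "ratio": r_q / r_a,
        "abs_log2_diff": abs(math.log2(r_q) - math.log2(r_a)),
    }
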