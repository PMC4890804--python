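"""Parametric Analysis of Gene set Enrichment (PAGE).

For a gene-level score vector (here Z-ratios of one comparison) and a
collection of gene sets, PAGE scores each set with

    Z = (Sm - mu) * sqrt(m) / delta

where ``Sm`` is the mean score of the ``m`` set members present in the
vector and ``mu``, ``delta`` are the mean and standard deviation of the
whole vector.  Under the null of a randomly drawn set, Z is approximately
standard normal (central limit theorem), so a two-sided normal p-value is
attached, with Benjamini-Hochberg adjustment across the reported sets.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr
from .io import GeneSetCollection

__all__ = ["page_enrichment", "geometric_average_change"]

#: Sets smaller than this (after intersection with the score vector) are
#: skipped: the normal approximation behind PAGE degrades for small m.
DEFAULT_MIN_SIZE = 10


def page_enrichment(
    zratios: pd.Series,
    sets: GeneSetCollection,
    min_size: int = DEFAULT_MIN_SIZE,
) -> pd.DataFrame:
    """Score every gene set against a per-gene Z-ratio vector.

    Parameters
    ----------
    zratios
        Scores indexed by gene identifier; missing entries are dropped.
    sets
        The gene-set collection; members absent from ``zratios`` are ignored
        (intersection semantics).
    min_size
        Minimum number of members with data; smaller sets are omitted and
        listed in ``result.attrs["skipped_sets"]``.

    Returns
    -------
    DataFrame indexed by set name with columns ``m``, ``s_m``, ``z_page``,
    ``p_page``, ``q_page`` and ``direction``; ``attrs`` carry ``mu``,
    ``delta`` and the skipped sets.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    scores = zratios.dropna()
    if scores.index.has_duplicates:
        raise ValueError("zratios index contains duplicate gene identifiers")
    mu = float(scores.mean())
    delta = float(scores.std(ddof=1))
    if not np.isfinite(delta) or delta == 0:
        raise ValueError("score vector has zero variance; PAGE undefined")

    rows = []
    skipped: list[str] = []
    for name in sets.names():
        members = [g for g in sets.members(name) if g in scores.index]
        m = len(members)
        if m < min_size:
            skipped.append(name)
            continue
        s_m = float(scores.loc[members].mean())
        z = (s_m - mu) * math.sqrt(m) / delta
        rows.append((name, m, s_m, z))

    if not rows:
        result = pd.DataFrame(
            columns=["m", "s_m", "z_page", "p_page", "q_page", "direction"]
        )
    else:
        result = pd.DataFrame(
            rows, columns=["set_name", "m", "s_m", "z_page"]
        ).set_index("set_name")
        result["p_page"] = 2.0 * stats.norm.sf(result["z_page"].abs())
        result["q_page"] = bh_fdr(result["p_page"])
        result["direction"] = np.where(result["z_page"] >= 0, "up", "down")
    result.attrs["mu"] = mu
    result.attrs["delta"] = delta
    result.attrs["skipped_sets"] = skipped
    return result


def geometric_average_change(
    values: pd.Series | dict[str, float],
    members: list[str] | tuple[str, ...] | None = None,
) -> float:
    """Sign-preserving geometric average of signed fold changes.

    The magnitude is ``exp(mean(log|v|))`` over the (non-zero) member values;
    the sign is the sign of the mean of the direction-signed log magnitudes
    ``sign(v) * log|v|``.  A zero mean signed log (perfectly balanced up and
    down regulation) returns +1.0 - no net change.  Zero-valued members are
    excluded.
    """
    series = pd.Series(values, dtype=float)
    if members is not None:
        series = series.loc[[g for g in members if g in series.index]]
    series = series.dropna()
    series = series[series != 0]
    if series.empty:
        raise ValueError("no usable member values for geometric average")
    log_mag = np.log(series.abs())
    signed = np.sign(series) * log_mag
    magnitude = float(np.exp(log_mag.mean()))
    s = float(signed.mean())
    if s > 0:
        return magnitude
    if s < 0:
        return -magnitude
    return 1.0
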