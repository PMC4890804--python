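"""Independent brute-force recomputations used as oracles in the tests.

Everything here is written directly from the definitions with plain Python
loops and closed-form distribution functions, deliberately not sharing any
code path with the package.
"""

from __future__ import annotations

import math
from itertools import combinations


def normal_two_sided_p(z: float) -> float:
    return math.erfc(abs(z) / math.sqrt(2.0))


def mean(xs) -> float:
    xs = list(xs)
    return sum(xs) / len(xs)


def sd(xs) -> float:
    xs = list(xs)
    m = mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def zscore_columns(values: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
    """values[sample][probe] -> per-sample standardized copy."""
    out: dict[str, dict[str, float]] = {}
    for sample, col in values.items():
        m, s = mean(col.values()), sd(col.values())
        out[sample] = {p: (v - m) / s for p, v in col.items()}
    return out


def bh_stepup(pvalues: list[float]) -> list[float]:
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    q = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, n * pvalues[i] / rank_from_top)
        q[i] = running
    return q


def oneway_anova(groups: list[list[float]]) -> tuple[float, float]:
    """Textbook sums-of-squares one-way ANOVA; p via the F survival function."""
    from scipy.stats import f as f_dist

    k = len(groups)
    all_vals = [x for g in groups for x in g]
    n_total = len(all_vals)
    grand = mean(all_vals)
    ssb = sum(len(g) * (mean(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - mean(g)) ** 2 for x in g) for g in groups)
    df_b, df_w = k - 1, n_total - k
    f = (ssb / df_b) / (ssw / df_w)
    return f, float(f_dist.sf(f, df_b, df_w))


def comparison_oracle(
    raw: dict[str, dict[str, float]],
    design: dict[str, str],
    group_a: str,
    group_b: str,
    all_groups: list[str],
    log_base: float = 10.0,
    floor: float = 1.0,
) -> dict[str, dict[str, float]]:
    """Every ComparisonResult field from scratch.

    ``raw[sample][probe]`` are raw intensities; returns per-probe dicts with
    keys mean_z_a, mean_z_b, delta_z, z_ratio, avg_z, fold_change, p_z, q,
    p_anova.
    """
    logged = {
        s: {p: math.log(max(v, floor), log_base) for p, v in col.items()}
        for s, col in raw.items()
    }
    z = zscore_columns(logged)
    probes = sorted(next(iter(raw.values())).keys())
    samples_of = lambda g: [s for s, lab in design.items() if lab == g]
    sa, sb = samples_of(group_a), samples_of(group_b)

    result: dict[str, dict[str, float]] = {}
    deltas = {}
    for p in probes:
        ma = mean(z[s][p] for s in sa)
        mb = mean(z[s][p] for s in sb)
        deltas[p] = ma - mb
        ra = mean(raw[s][p] for s in sa)
        rb = mean(raw[s][p] for s in sb)
        ratio = ra / rb
        result[p] = {
            "mean_z_a": ma,
            "mean_z_b": mb,
            "delta_z": ma - mb,
            "avg_z": mean(z[s][p] for s in sa + sb),
            "fold_change": ratio if ratio >= 1 else -1.0 / ratio,
        }
    denom = sd(deltas.values())
    for p in probes:
        result[p]["z_ratio"] = deltas[p] / denom
        result[p]["p_z"] = normal_two_sided_p(result[p]["z_ratio"])
    qs = bh_stepup([result[p]["p_z"] for p in probes])
    for p, q in zip(probes, qs):
        result[p]["q"] = q
    for p in probes:
        groups_vals = [[z[s][p] for s in samples_of(g)] for g in all_groups]
        result[p]["p_anova"] = oneway_anova(groups_vals)[1]
    return result


def page_oracle(
    scores: dict[str, float], sets: dict[str, list[str]], min_size: int
) -> dict[str, tuple[int, float, float, float]]:
    """set name -> (m, Sm, Z_page, p_page) straight from the formula."""
    mu = mean(scores.values())
    delta = sd(scores.values())
    out = {}
    for name, members in sets.items():
        present = [g for g in members if g in scores]
        m = len(present)
        if m < min_size:
            continue
        s_m = mean(scores[g] for g in present)
        z = (s_m - mu) * math.sqrt(m) / delta
        out[name] = (m, s_m, z, normal_two_sided_p(z))
    return out


def venn_region_oracle(
    sets: dict[str, set[str]]
) -> dict[frozenset, set[str]]:
    """Exhaustive membership scan: every gene into its exact region."""
    labels = list(sets)
    regions: dict[frozenset, set[str]] = {
        frozenset(c): set()
        for r in (1, 2, 3)
        for c in combinations(labels, r)
    }
    for gene in set().union(*sets.values()):
        key = frozenset(l for l in labels if gene in sets[l])
        regions[key].add(gene)
    return regions
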