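"""Synthetic data with the statistical structure the pipeline assumes.

The expression generator emulates a 4-group (sham, PHEN, mTBI, mTBI_PHEN),
n=5-per-group bead-array experiment: probe log10 intensities are drawn from
a log-normal baseline, per-array scale/offset distortions are applied as an
affine transform of the log intensities (exactly what per-array Z-scoring
removes), and differential expression is planted as per-group log10 fold
shifts on a designated subset of probes.  Planted probes are drawn from a
well-expressed baseline tier, mirroring the fact that array-validated
differential genes are robustly expressed transcripts; the pipeline's
average-Z expression filter makes sensitivity claims meaningful only there.

Companion generators produce gene-set collections with planted coherent
shifts, qPCR Ct tables from true expression ratios under the Pfaffl model,
and behavioral trials from group mean discrimination indices.

All randomness flows from a single integer master seed; each component uses
an independently spawned child stream, so switching one component's noise
off never perturbs another's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, SampleDesign

__all__ = [
    "SimulationConfig",
    "simulate_expression",
    "simulate_gene_sets",
    "simulate_qpcr",
    "simulate_behavior",
    "design_from_config",
    "recovery_effect_layout",
]

DEFAULT_GROUPS = {"sham": 5, "PHEN": 5, "mTBI": 5, "mTBI_PHEN": 5}

#: Venn patterns of the standard recovery layout: (treated groups carrying the
#: effect, number of up-regulated probes, number of down-regulated probes).
RECOVERY_PATTERNS = [
    (("mTBI", "mTBI_PHEN", "PHEN"), 15, 15),  # commonly regulated
    (("mTBI",), 15, 15),                      # injury-exclusive
    (("mTBI", "mTBI_PHEN"), 10, 10),          # injury with/without treatment
    (("PHEN",), 10, 10),                      # drug-exclusive
]


def recovery_effect_layout(
    fold_up: float = 2.0,
    fold_down: float = 0.5,
    width: int = 5,
) -> tuple[dict[str, dict[str, float]], dict[str, tuple[frozenset, str]]]:
    """The standard 100-probe planted-effect layout for recovery studies.

    Probes are spread over four Venn patterns (common to all three
    treatment-vs-sham comparisons, injury-exclusive, injury-plus-treatment,
    drug-exclusive), half up- and half down-regulated per pattern.  Returns
    the ``effects`` mapping for :class:`SimulationConfig` and a truth mapping
    ``probe_id -> (frozenset of comparison labels, direction)`` naming each
    probe's expected signed Venn region.
    """
    effects: dict[str, dict[str, float]] = {}
    regions: dict[str, tuple[frozenset, str]] = {}
    i = 0
    for groups, n_up, n_down in RECOVERY_PATTERNS:
        for direction, count, fold in (
            ("up", n_up, fold_up),
            ("down", n_down, fold_down),
        ):
            for _ in range(count):
                i += 1
                pid = f"P{i:0{width}d}"
                effects[pid] = {g: fold for g in groups}
                regions[pid] = (
                    frozenset(f"{g}_vs_sham" for g in groups),
                    direction,
                )
    return effects, regions


@dataclass
class SimulationConfig:
    """Parameters of the synthetic expression experiment.

    Units: all location/scale parameters are on the log10-intensity scale.

    Parameters
    ----------
    n_probes
        Array size; default 25,000 probes.
    groups
        Ordered group label -> replicate count; first group is the control.
    baseline_mean, baseline_sd
        Log10 intensity distribution of unplanted probes.
    planted_baseline_mean, planted_baseline_sd
        Baseline tier for probes carrying planted effects (well-expressed).
    noise_sd
        Within-group biological + technical noise sd.
    array_scale_sd, array_offset_sd
        Per-array affine distortion of log intensities: each array j applies
        ``x -> (1 + s_j) * x + o_j``.
    effects
        ``probe_id -> {group: fold}``; folds are raw-scale ratios vs the
        control group (fold 2.0 plants +log10(2) in that group).
    seed
        Master seed; identical config + seed gives identical output.
    """

    n_probes: int = 25_000
    groups: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    baseline_mean: float = 2.5
    baseline_sd: float = 0.5
    planted_baseline_mean: float = 3.25
    planted_baseline_sd: float = 0.2
    noise_sd: float = 0.1
    array_scale_sd: float = 0.05
    array_offset_sd: float = 0.1
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 2:
            raise ValueError("n_probes must be >= 2")
        for g, n in self.groups.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples, got {n}")
        ids = set(self.probe_ids())
        for pid, per_group in self.effects.items():
            if pid not in ids:
                raise ValueError(f"planted probe {pid!r} outside probe range")
            for g, fold in per_group.items():
                if g not in self.groups:
                    raise ValueError(f"planted group {g!r} not in design")
                if fold <= 0:
                    raise ValueError(f"fold for {pid!r}/{g!r} must be > 0")

    def probe_ids(self) -> list[str]:
        width = max(5, len(str(self.n_probes)))
        return [f"P{i:0{width}d}" for i in range(1, self.n_probes + 1)]

    @property
    def control_group(self) -> str:
        return next(iter(self.groups))


def design_from_config(cfg: SimulationConfig) -> SampleDesign:
    assignment = {
        f"{g}_{k + 1}": g for g, n in cfg.groups.items() for k in range(n)
    }
    return SampleDesign(assignment, list(cfg.groups))


def _truth_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Planted probes with per-group folds and per-comparison directions."""
    control = cfg.control_group
    treat_groups = [g for g in cfg.groups if g != control]
    rows = []
    for pid, per_group in sorted(cfg.effects.items()):
        row: dict[str, object] = {"probe_id": pid}
        for g in treat_groups:
            fold = per_group.get(g, 1.0)
            row[f"fold_{g}"] = fold
            row[f"direction_{g}"] = (
                "up" if fold > 1 else "down" if fold < 1 else "none"
            )
        rows.append(row)
    cols = ["probe_id"] + [
        c for g in treat_groups for c in (f"fold_{g}", f"direction_{g}")
    ]
    return pd.DataFrame(rows, columns=cols).set_index("probe_id")


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a raw probe-by-sample intensity matrix and its truth table.

    Raw intensity of probe i on array j is
    ``10 ** ((1 + s_j) * (b_i + g_ig + e_ij) + o_j)`` with baseline ``b_i``,
    planted group effect ``g_ig = log10(fold)``, noise ``e_ij`` and the
    array's affine distortion ``(s_j, o_j)``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_base, rng_noise, rng_array = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    probe_ids = cfg.probe_ids()
    design = design_from_config(cfg)
    samples = design.sample_ids
    n, p = len(probe_ids), len(samples)

    baseline = rng_base.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    planted_pos = {pid: i for i, pid in enumerate(probe_ids) if pid in cfg.effects}
    if planted_pos:
        idx = np.fromiter(planted_pos.values(), dtype=int)
        baseline[idx] = rng_base.normal(
            cfg.planted_baseline_mean, cfg.planted_baseline_sd, size=len(idx)
        )

    group_effect = np.zeros((n, p))
    for pid, per_group in cfg.effects.items():
        i = planted_pos[pid]
        for g, fold in per_group.items():
            cols = [samples.index(s) for s in design.samples_in(g)]
            group_effect[i, cols] = math.log10(fold)

    noise = rng_noise.normal(0.0, 1.0, size=(n, p)) * cfg.noise_sd
    scale = 1.0 + rng_array.normal(0.0, 1.0, size=p) * cfg.array_scale_sd
    offset = rng_array.normal(0.0, 1.0, size=p) * cfg.array_offset_sd

    log10_clean = baseline[:, None] + group_effect + noise
    log10_obs = scale[None, :] * log10_clean + offset[None, :]
    raw = 10.0**log10_obs

    frame = pd.DataFrame(raw, index=probe_ids, columns=samples)
    return ExpressionMatrix(frame, scale="raw"), _truth_table(cfg)


def simulate_gene_sets(
    truth: pd.DataFrame,
    probe_ids: list[str],
    group: str,
    n_sets: int = 20,
    set_size: int = 20,
    n_enriched: int = 4,
    planted_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Random gene sets, some enriched for planted probes of one direction.

    Each enriched set draws ``planted_fraction`` of its members from probes
    planted up (or down, alternating) in ``group``; the remainder, and all
    null sets, are drawn from unplanted probes.  Returns the collection and
    a truth frame (set_name, enriched, direction).
    """
    if set_size > len(probe_ids):
        raise ValueError("set size exceeds number of probes")
    if n_enriched > n_sets:
        raise ValueError("n_enriched exceeds n_sets")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dir_col = f"direction_{group}"
    up = truth.index[truth[dir_col] == "up"].tolist() if len(truth) else []
    down = truth.index[truth[dir_col] == "down"].tolist() if len(truth) else []
    planted = set(truth.index)
    null_pool = [p for p in probe_ids if p not in planted]

    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    rows = []
    for k in range(n_sets):
        name = f"SET{k + 1:03d}"
        if k < n_enriched:
            direction = "up" if k % 2 == 0 else "down"
            pool = up if direction == "up" else down
            n_sig = min(int(round(planted_fraction * set_size)), len(pool))
            if n_sig == 0:
                raise ValueError(
                    f"no planted {direction!r} probes available for enriched set"
                )
            members = list(rng.choice(pool, size=n_sig, replace=False))
            members += list(
                rng.choice(null_pool, size=set_size - n_sig, replace=False)
            )
            rows.append({"set_name": name, "enriched": True, "direction": direction})
        else:
            members = list(rng.choice(null_pool, size=set_size, replace=False))
            rows.append({"set_name": name, "enriched": False, "direction": "none"})
        sets[name] = ("synthetic", tuple(members))
    truth_frame = pd.DataFrame(
        rows, columns=["set_name", "enriched", "direction"]
    ).set_index("set_name")
    return GeneSetCollection(sets), truth_frame


def simulate_qpcr(
    true_ratios: dict[str, float],
    efficiencies: dict[str, float] | None = None,
    reference: str = "Gapdh",
    n_per_group: int = 5,
    sd_ct: float = 0.1,
    control_group: str = "sham",
    treated_group: str = "mTBI",
    ct_mean: float = 24.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format qPCR Ct table realizing given true expression ratios.

    For each target gene, treated-group Cts center at
    ``control mean - log_E(ratio)`` (fewer cycles = more template); the
    reference gene's true ratio is fixed at 1.  ``sd_ct = 0`` gives exact
    recovery of the planted ratios by the Pfaffl arithmetic.
    """
    efficiencies = efficiencies or {}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = dict(true_ratios)
    genes.setdefault(reference, 1.0)
    records = []
    for gene, ratio in genes.items():
        if ratio <= 0:
            raise ValueError(f"true ratio for {gene!r} must be > 0")
        e = efficiencies.get(gene, 2.0)
        shift = math.log(ratio) / math.log(e)
        for group, center in (
            (control_group, ct_mean),
            (treated_group, ct_mean - shift),
        ):
            cts = center + rng.normal(0.0, 1.0, size=n_per_group) * sd_ct
            for k, ct in enumerate(cts):
                records.append(
                    {
                        "gene": gene,
                        "sample": f"{group}_{k + 1}",
                        "group": group,
                        "Ct": float(ct),
                        "role": "reference" if gene == reference else "target",
                    }
                )
    return pd.DataFrame(records)


def simulate_behavior(
    group_means: dict[str, float],
    sd: float = 0.2,
    n_per_group: int = 18,
    paradigm: str = "NOR",
    total_time: float = 40.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Behavioral trial table from group mean discrimination indices.

    Indices are drawn normally per group (clipped to (-1, 1)) and converted
    back to exploration times with a fixed per-trial total, so
    ``preference_index`` recovers them exactly.
    """
    if not -1 < min(group_means.values()) <= max(group_means.values()) < 1:
        raise ValueError("group mean indices must lie in (-1, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for group, mu in group_means.items():
        idx = np.clip(
            mu + rng.normal(0.0, 1.0, size=n_per_group) * sd, -0.999, 0.999
        )
        for k, i in enumerate(idx):
            rows.append(
                {
                    "animal": f"{group}_{k + 1}",
                    "group": group,
                    "paradigm": paradigm,
                    "t_novel": total_time * (1 + i) / 2,
                    "t_familiar": total_time * (1 - i) / 2,
                }
            )
    return pd.DataFrame(rows)
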