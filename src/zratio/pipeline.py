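"""End-to-end orchestration: matrix -> comparisons -> enrichment -> Venn.

``run_pipeline`` is a pure function of (inputs, config): it loads the
expression matrix and design, runs the Z-score/Z-ratio chain for each
configured group-vs-control comparison, scores gene-set collections with
PAGE, partitions the significant lists into a signed Venn report, scans a
comparison pair for reversal genes, and writes everything as TSV/JSON plus
a manifest of counts, thresholds and warnings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import diffexp, page, venn
from .io import (
    ExpressionMatrix,
    SampleDesign,
    read_design,
    read_expression_matrix,
    read_gene_sets,
)

__all__ = ["RunConfig", "run_pipeline", "significant_lists"]

DEFAULT_COMPARISONS = [
    ("mTBI", "sham"),
    ("mTBI_PHEN", "sham"),
    ("PHEN", "sham"),
]

RESULT_COLUMNS = [
    "z_ratio",
    "fold_change",
    "p_z",
    "q",
    "p_anova",
    "avg_z",
    "delta_z",
    "mean_z_a",
    "mean_z_b",
    "significant",
    "direction",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    expression_path: str
    design_path: str
    out_dir: str
    dialect: str = "tsv"
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_COMPARISONS)
    )
    thresholds: diffexp.SelectionThresholds = field(
        default_factory=diffexp.SelectionThresholds
    )
    gmt_paths: list[str] = field(default_factory=list)
    min_set_size: int = page.DEFAULT_MIN_SIZE
    log_base: float = 10.0
    floor: float = 1.0
    reversal_pair: tuple[str, str] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = diffexp.SelectionThresholds(**raw["thresholds"])
        if "comparisons" in raw:
            raw["comparisons"] = [tuple(c) for c in raw["comparisons"]]
        if raw.get("reversal_pair"):
            raw["reversal_pair"] = tuple(raw["reversal_pair"])
        return cls(**raw)


def _comparison_label(group_a: str, group_b: str) -> str:
    return f"{group_a}_vs_{group_b}"


def significant_lists(
    tables: dict[str, "object"],
) -> list[venn.SignedGeneList]:
    """Signed up/down lists from per-comparison result tables."""
    out = []
    for label, table in tables.items():
        out.append(
            venn.SignedGeneList(
                label=label,
                up=set(table.index[table["direction"] == "up"]),
                down=set(table.index[table["direction"] == "down"]),
            )
        )
    return out


def run_comparisons(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    comparisons: list[tuple[str, str]],
    thresholds: diffexp.SelectionThresholds | None = None,
    log_base: float = 10.0,
    floor: float = 1.0,
) -> dict[str, "object"]:
    """Run the differential-expression chain for every comparison.

    Returns ``label -> comparison table``; the per-probe ANOVA across all
    design groups is computed once and shared.
    """
    logged = diffexp.log_transform(matrix, base=log_base, floor=floor)
    z = diffexp.zscore_normalize(logged)
    anova = diffexp.anova_pvalues(z, design)
    tables = {}
    for group_a, group_b in comparisons:
        tables[_comparison_label(group_a, group_b)] = diffexp.compare(
            z,
            design,
            group_a,
            group_b,
            raw=matrix,
            thresholds=thresholds,
            anova=anova,
        )
    return tables


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write outputs; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = read_expression_matrix(cfg.expression_path, dialect=cfg.dialect)
    design = read_design(cfg.design_path)
    for a, b in cfg.comparisons:
        design.require_groups(a, b, min_size=2)

    tables = run_comparisons(
        matrix,
        design,
        cfg.comparisons,
        thresholds=cfg.thresholds,
        log_base=cfg.log_base,
        floor=cfg.floor,
    )

    manifest: dict = {
        "thresholds": asdict(cfg.thresholds),
        "comparisons": {},
        "seed": cfg.seed,
        "warnings": {},
    }

    for label, table in tables.items():
        cols = [c for c in RESULT_COLUMNS if c in table.columns]
        table[cols].to_csv(out / f"diffexp_{label}.tsv", sep="\t",
                           index_label="probe_id")
        manifest["comparisons"][label] = {
            "n_probes": int(len(table)),
            "n_significant": int(table["significant"].sum()),
            "n_up": int((table["direction"] == "up").sum()),
            "n_down": int((table["direction"] == "down").sum()),
        }
        excluded = table.attrs.get("excluded_probes", [])
        if excluded:
            manifest["warnings"][label] = {"excluded_probes": len(excluded)}

    # PAGE enrichment per comparison per collection
    enrichment_counts: dict[str, dict] = {}
    for gmt_path in cfg.gmt_paths:
        collection = read_gene_sets(gmt_path)
        stem = Path(gmt_path).stem
        for label, table in tables.items():
            result = page.page_enrichment(
                table["z_ratio"], collection, min_size=cfg.min_set_size
            )
            result.to_csv(
                out / f"page_{stem}_{label}.tsv", sep="\t", index_label="set_name"
            )
            enrichment_counts[f"{stem}/{label}"] = {
                "n_sets_scored": int(len(result)),
                "n_sets_skipped": len(result.attrs.get("skipped_sets", [])),
            }
    manifest["enrichment"] = enrichment_counts

    # Signed Venn partition over exactly three comparisons
    lists = significant_lists(tables)
    if len(lists) == 3:
        partition = venn.partition_signed(lists)
        with open(out / "venn.json", "w", encoding="utf-8") as fh:
            json.dump(partition.to_dict(), fh, indent=2)
        manifest["venn_counts"] = partition.counts()

    # Reversal genes for a chosen comparison pair
    if cfg.reversal_pair:
        by_label = {l.label: l for l in lists}
        a, b = cfg.reversal_pair
        if a not in by_label or b not in by_label:
            raise ValueError(f"reversal pair {cfg.reversal_pair} not among comparisons")
        rev = sorted(venn.reversal_genes(by_label[a], by_label[b]))
        with open(out / "reversal.json", "w", encoding="utf-8") as fh:
            json.dump({"pair": [a, b], "genes": rev}, fh, indent=2)
        manifest["n_reversal_genes"] = len(rev)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
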