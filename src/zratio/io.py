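"""Readers, writers and validated containers for the pipeline's external formats.

Expression matrices are plain TSV (or GEO series-matrix text), gene sets are
GMT, sample designs are two-column TSV.  Everything is validated on load:
duplicate identifiers, non-numeric cells and malformed lines raise
:class:`FormatError` with coordinates rather than being silently coerced.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "SampleDesign",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_design",
    "write_design",
    "collapse_to_genes",
]

#: Strings treated as missing values in all tabular inputs.
NA_VALUES = ("", "NA")


class FormatError(ValueError):
    """An input file violates its format contract (duplicates, bad cells...)."""


@dataclass
class ExpressionMatrix:
    """Probe-by-sample intensity matrix.

    Parameters
    ----------
    data
        ``probes x samples`` DataFrame; index are probe ids, columns sample
        ids.  ``NaN`` marks a missing measurement.
    scale
        ``"raw"`` for non-negative scanner intensities, ``"log"`` after log
        transformation.
    log_base
        Base used by :func:`zratio.diffexp.log_transform`; ``None`` on raw
        matrices.
    """

    data: pd.DataFrame
    scale: str = "raw"
    log_base: float | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log"):
            raise ValueError(f"scale must be 'raw' or 'log', got {self.scale!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe id(s): {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample id(s): {dup}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if self.scale == "raw":
            finite = values[np.isfinite(values)]
            if finite.size and finite.min() < 0:
                raise FormatError("raw intensities must be non-negative")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SampleDesign:
    """Assignment of samples to treatment groups.

    ``groups`` preserves first-appearance order of the design file; the first
    group is conventionally the control (sham) group.
    """

    assignment: dict[str, str]
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for g in self.assignment.values():
            if g not in seen:
                seen.append(g)
        if not self.groups:
            self.groups = seen
        elif set(self.groups) != set(seen):
            raise FormatError("group list does not match assignment groups")
        if len(self.groups) < 1:
            raise FormatError("design must contain at least one group")

    def samples_in(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"unknown group label: {group!r}")
        return [s for s, g in self.assignment.items() if g == group]

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.samples_in(g)) for g in self.groups}

    def require_groups(self, *labels: str, min_size: int = 2) -> None:
        """Raise unless every requested group exists with >= min_size samples."""
        for lab in labels:
            n = len(self.samples_in(lab))  # KeyError if unknown
            if n < min_size:
                raise ValueError(
                    f"group {lab!r} has {n} sample(s); >= {min_size} required"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignment)


@dataclass
class GeneSetCollection:
    """Named gene sets: ``name -> (description, members)`` with unique members."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def _frame_from_table(text: str, source: str) -> pd.DataFrame:
    df = pd.read_csv(
        _stdio.StringIO(text),
        sep="\t",
        index_col=0,
        na_values=list(NA_VALUES),
        keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')
    out = {}
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            probe = bad.index[0]
            raise FormatError(
                f"{source}: non-numeric value {bad.iloc[0]!r} at probe "
                f"{probe!r}, sample {col!r}"
            ) from None
    frame = pd.DataFrame(out, index=df.index)
    frame.index.name = None
    return frame


def read_expression_matrix(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a probe-by-sample intensity matrix.

    ``dialect="tsv"`` expects a header row of sample ids with probe ids in the
    first column.  ``dialect="geo_series_matrix"`` additionally strips ``!``
    metadata lines and reads the table between the
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers, the
    layout used by GEO series-matrix exports.
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    if dialect == "geo_series_matrix":
        lines = text.splitlines()
        try:
            start = next(
                i for i, l in enumerate(lines)
                if l.lower().startswith("!series_matrix_table_begin")
            )
            end = next(
                i for i, l in enumerate(lines)
                if l.lower().startswith("!series_matrix_table_end")
            )
        except StopIteration:
            raise FormatError(
                f"{path}: series_matrix_table_begin/end markers not found"
            ) from None
        text = "\n".join(lines[start + 1:end])
    elif dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    frame = _frame_from_table(text, str(path))
    return ExpressionMatrix(frame, scale="raw")


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: ``name <TAB> description <TAB> member...`` per line."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = tuple(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------

def read_design(path) -> SampleDesign:
    """Read a two-column (sample_id, group) TSV with a header row.

    A sample listed twice with the same group is deduplicated; two different
    groups for one sample is a format error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: design needs two columns (sample_id, group)")
    assignment: dict[str, str] = {}
    groups: list[str] = []
    for _, row in df.iterrows():
        sample, group = str(row.iloc[0]), str(row.iloc[1])
        if sample in assignment and assignment[sample] != group:
            raise FormatError(
                f"{path}: sample {sample!r} assigned to both "
                f"{assignment[sample]!r} and {group!r}"
            )
        assignment[sample] = group
        if group not in groups:
            groups.append(group)
    return SampleDesign(assignment, groups)


def write_design(design: SampleDesign, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in design.assignment.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# Probe -> gene collapse
# ---------------------------------------------------------------------------

def collapse_to_genes(
    matrix: ExpressionMatrix, probe_to_gene: dict[str, str]
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    For every gene the probe with the highest mean log intensity across all
    samples is kept (on a raw matrix the mean of log10 intensities is used for
    ranking; values are not transformed).  Probes without a mapping are
    dropped.
    """
    data = matrix.data
    mapped = [p for p in data.index if p in probe_to_gene]
    if not mapped:
        raise ValueError("no probe has a gene mapping")
    sub = data.loc[mapped]
    if matrix.scale == "raw":
        rank_vals = np.log10(np.maximum(sub.to_numpy(dtype=float), 1.0))
    else:
        rank_vals = sub.to_numpy(dtype=float)
    score = pd.Series(np.nanmean(rank_vals, axis=1), index=sub.index)
    genes = pd.Series({p: probe_to_gene[p] for p in mapped})
    best = (
        pd.DataFrame({"gene": genes, "score": score})
        .sort_values(["gene", "score"], ascending=[True, False])
        .drop_duplicates("gene")
    )
    collapsed = sub.loc[best.index]
    collapsed.index = best["gene"].to_numpy()
    return ExpressionMatrix(collapsed, scale=matrix.scale, log_base=matrix.log_base)
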