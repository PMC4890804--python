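"""Signed three-way Venn partitioning of significant-gene lists.

Each group-vs-control comparison yields an up list and a down list of gene
identifiers.  The three comparisons are partitioned into the seven regions
of a classic 3-set Venn diagram, independently for each direction, matching
the paired up/down counts reported for such designs.  A reversal scan
(up in one comparison, down in the other) identifies genes whose
injury-induced regulation a treatment reverses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

__all__ = ["SignedGeneList", "VennPartition", "partition_signed", "reversal_genes"]


@dataclass
class SignedGeneList:
    """Up- and down-regulated gene identifiers of one comparison."""

    label: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.up = set(self.up)
        self.down = set(self.down)
        overlap = self.up & self.down
        if overlap:
            raise ValueError(
                f"{self.label}: gene(s) in both directions: {sorted(overlap)}"
            )


@dataclass
class VennPartition:
    """Region -> direction -> gene set for a 3-comparison Venn diagram.

    Region keys are frozensets of comparison labels; a gene in region
    ``{A, B}`` (direction "up") is up-regulated in exactly comparisons A
    and B.
    """

    labels: tuple[str, str, str]
    regions: dict[frozenset, dict[str, set[str]]]

    def genes(self, labels, direction: str) -> set[str]:
        return set(self.regions[frozenset(labels)][direction])

    def counts(self) -> dict[str, dict[str, int]]:
        """Region name ("A&B" style, labels joined in input order) -> counts."""
        out = {}
        for key, dirs in self.regions.items():
            name = "&".join(l for l in self.labels if l in key)
            out[name] = {d: len(g) for d, g in dirs.items()}
        return out

    def to_dict(self) -> dict:
        """JSON-ready report with sorted gene lists per region/direction."""
        report = {}
        for key, dirs in self.regions.items():
            name = "&".join(l for l in self.labels if l in key)
            report[name] = {d: sorted(g) for d, g in dirs.items()}
        return {"labels": list(self.labels), "regions": report}


def _partition_one_direction(sets: dict[str, set[str]]) -> dict[frozenset, set[str]]:
    labels = list(sets)
    regions: dict[frozenset, set[str]] = {}
    for r in (1, 2, 3):
        for inside in combinations(labels, r):
            key = frozenset(inside)
            genes = set.intersection(*(sets[l] for l in inside))
            for l in labels:
                if l not in key:
                    genes = genes - sets[l]
            regions[key] = genes
    return regions


def partition_signed(lists: list[SignedGeneList]) -> VennPartition:
    """Partition exactly three signed gene lists into the 7 Venn regions.

    Up and down directions are partitioned separately: a gene up in one
    comparison and down in another contributes to both direction-specific
    diagrams.
    """
    if len(lists) != 3:
        raise ValueError(f"exactly 3 comparisons required, got {len(lists)}")
    labels = tuple(l.label for l in lists)
    if len(set(labels)) != 3:
        raise ValueError(f"duplicate comparison labels: {labels}")
    up = _partition_one_direction({l.label: l.up for l in lists})
    down = _partition_one_direction({l.label: l.down for l in lists})
    regions = {key: {"up": up[key], "down": down[key]} for key in up}
    return VennPartition(labels=labels, regions=regions)


def reversal_genes(a: SignedGeneList, b: SignedGeneList) -> set[str]:
    """Genes regulated in opposite directions in two comparisons.

    Returns ``(a.up & b.down) | (a.down & b.up)`` - the signature of a
    treatment reversing an injury-induced regulation.
    """
    return (a.up & b.down) | (a.down & b.up)
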