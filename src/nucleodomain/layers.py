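"""Genome layer algebra: the NAD-only / NAD/LAD / LAD-only / iNAD/iLAD
partition, overlap fractions, cell-type-specific domains and relocation
fates.

All classifications are base-pair-level set algebra, so the four layers are
mutually disjoint and tile the genome exactly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import DomainSet

LAYERS = ("NAD-only", "NAD/LAD", "LAD-only", "iNAD/iLAD")


@dataclass
class LayerPartition:
    """The four mutually disjoint repressive-layer sets tiling the genome."""

    nad_only: DomainSet
    nad_lad: DomainSet
    lad_only: DomainSet
    neither: DomainSet  # iNAD/iLAD

    def __post_init__(self) -> None:
        genome = self.nad_only.genome
        total = sum(s.total_bp for s in self.sets.values())
        if total != genome.total_bp:
            raise ValueError("layer partition does not tile the genome")

    @property
    def sets(self) -> dict[str, DomainSet]:
        return {"NAD-only": self.nad_only, "NAD/LAD": self.nad_lad,
                "LAD-only": self.lad_only, "iNAD/iLAD": self.neither}

    @property
    def genome(self):
        return self.nad_only.genome

    def coverage(self) -> dict[str, float]:
        g = self.genome.total_bp
        return {k: s.total_bp / g for k, s in self.sets.items()}


def classify_layers(nads: DomainSet, lads: DomainSet) -> LayerPartition:
    """Partition the genome by nucleolus/lamina contact status."""
    if nads.genome != lads.genome:
        raise ValueError("mismatched genome contexts")
    nad_lad = nads.intersect(lads, name="NAD/LAD").relabel("NAD/LAD")
    nad_only = nads.subtract(lads, name="NAD-only").relabel("NAD-only")
    lad_only = lads.subtract(nads, name="LAD-only").relabel("LAD-only")
    union = pd.concat([nads.merge().df[["Chromosome", "Start", "End"]].assign(Label="n"),
                       lads.merge().df[["Chromosome", "Start", "End"]].assign(Label="l")],
                      ignore_index=True)
    both = DomainSet(union, nads.genome).merge()
    neither = both.complement(name="iNAD/iLAD").relabel("iNAD/iLAD")
    return LayerPartition(nad_only, nad_lad, lad_only, neither)


def overlap_fraction(a: DomainSet, b: DomainSet) -> float:
    """Percent of a's base pairs covered by b (asymmetric)."""
    if a.genome != b.genome:
        raise ValueError("mismatched genome contexts")
    a_bp = a.total_bp
    if a_bp == 0:
        raise ValueError("overlap fraction undefined for an empty set")
    return 100.0 * a.intersect_bp(b) / a_bp


def cell_specific(d1: DomainSet, d2: DomainSet, min_len: int = 100_000,
                  ) -> tuple[DomainSet, DomainSet, DomainSet]:
    """Split two cell types' domain sets into (specific-to-1, specific-to-2,
    shared); specific pieces shorter than min_len are dropped."""
    if d1.genome != d2.genome:
        raise ValueError("mismatched genome contexts")
    sp1 = d1.subtract(d2).filter_min_length(min_len).relabel(
        (d1.name or "set1") + "_sp")
    sp2 = d2.subtract(d1).filter_min_length(min_len).relabel(
        (d2.name or "set2") + "_sp")
    shared = d1.intersect(d2).relabel("shared")
    return sp1, sp2, shared


def relocation_fates(sources: dict[str, DomainSet],
                     target: LayerPartition) -> pd.DataFrame:
    """bp fraction of each source domain class landing in each target layer.

    Rows sum to 1; empty source classes are omitted (noted by absence).
    """
    rows = {}
    for name, src in sources.items():
        bp = src.total_bp
        if bp == 0:
            continue
        rows[name] = {layer: src.intersect_bp(tset) / bp
                      for layer, tset in target.sets.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(LAYERS))


def annotate_fraction(d: DomainSet, annotation: dict[str, DomainSet],
                      ) -> dict[str, float]:
    """bp fraction of a domain set per annotation class (e.g. early/late
    replication, A/B compartment); uncovered genome counts as "NA".

    Annotation classes must be mutually disjoint.
    """
    bp = d.total_bp
    if bp == 0:
        raise ValueError("empty domain set")
    out = {}
    covered = 0
    for label, aset in annotation.items():
        shared = d.intersect_bp(aset)
        out[label] = shared / bp
        covered += shared
    out["NA"] = (bp - covered) / bp
    if out["NA"] < 1e-12:
        out["NA"] = 0.0
    return out


def gene_density(d: DomainSet, genes: pd.DataFrame) -> float:
    """Genes per Mb: count of gene midpoints inside the set over its size.

    ``genes`` needs Chromosome/Start/End columns.
    """
    bp = d.total_bp
    if bp == 0:
        raise ValueError("gene density undefined for an empty set")
    mids = ((genes["Start"] + genes["End"]) // 2).to_numpy()
    chroms = genes["Chromosome"].to_numpy(dtype=object)
    inside = d.contains_points(chroms, mids)
    return float(inside.sum()) / (bp / 1e6)
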