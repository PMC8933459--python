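"""Signal aggregation: boundary metaprofiles, per-domain signal, 20-kb
fold-change tracks, and RPKM-based expression classes."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome
from .intervals import DomainSet
from .tracks import BinnedTrack, StepTrack


@dataclass
class BorderProfile:
    """Mean signal around domain boundaries, oriented interior-right."""

    matrix: np.ndarray      # boundaries x position bins
    positions: np.ndarray   # bin centers relative to the boundary (bp)
    flank: int
    bin: int
    n_dropped: int          # boundaries without full flanks

    @property
    def mean_curve(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


def border_profile(track: StepTrack, domains: DomainSet,
                   flank: int = 500_000, bin: int = 10_000) -> BorderProfile:
    """Average a signal over domain boundaries.

    Each domain contributes both boundaries; the left (start) boundary is
    used as-is and the right (end) boundary is mirrored, so the domain
    interior always lies on the positive side of the position axis.  Signal
    per position bin is the exact length-weighted mean.  Boundaries whose
    flanks extend beyond the chromosome are dropped (counted).
    """
    if flank <= 0 or bin <= 0 or flank % bin:
        raise ValueError("flank must be a positive multiple of bin")
    n_bins = 2 * flank // bin
    offsets = -flank + np.arange(n_bins) * bin
    rows = []
    dropped = 0
    for iv in domains.merge().df.itertuples(index=False):
        size = domains.genome.sizes[iv.Chromosome]
        for boundary, mirror in ((iv.Start, False), (iv.End, True)):
            if boundary - flank < 0 or boundary + flank > size:
                dropped += 1
                continue
            a = boundary + offsets
            vals = track.mean(iv.Chromosome, a, a + bin)
            rows.append(vals[::-1] if mirror else vals)
    if not rows:
        raise ValueError("no boundaries with full flanks inside chromosomes")
    return BorderProfile(np.vstack(rows), offsets + bin / 2, flank, bin, dropped)


def domain_signal(track: StepTrack, domains: DomainSet,
                  ) -> tuple[pd.DataFrame, dict]:
    """Length-weighted mean signal per domain plus a distribution summary."""
    if domains.is_empty:
        return pd.DataFrame(columns=["Chromosome", "Start", "End", "Mean"]), {}
    rows = []
    for iv in domains.df.itertuples(index=False):
        mean = float(track.mean(iv.Chromosome, iv.Start, iv.End))
        rows.append((iv.Chromosome, iv.Start, iv.End, mean))
    df = pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "Mean"])
    q = df["Mean"].quantile([0.25, 0.5, 0.75])
    summary = dict(mean=float(df["Mean"].mean()), median=float(q[0.5]),
                   q1=float(q[0.25]), q3=float(q[0.75]), n=len(df))
    return df, summary


def binned_fold_change(cond_a: StepTrack, cond_b: StepTrack,
                       bin: int = 20_000, pseudocount: float = 1.0,
                       ) -> tuple[BinnedTrack, pd.DataFrame]:
    """Per-bin log2 fold change of two coverage tracks.

    Reads per bin are normalized by each condition's library size (the
    genome-wide coverage integral) before the ratio; the pseudocount (in
    reads) is placed on the normalized scale as psi / sqrt(A * B), which
    keeps the fold change exactly antisymmetric under condition swap and
    exactly zero when the normalized signals agree.
    Returns the fold-change track and the paired per-bin values for
    scatter plots.
    """
    if bin <= 0:
        raise ValueError("bin size must be positive")
    if cond_a.genome != cond_b.genome:
        raise ValueError("mismatched genomes")
    genome = cond_a.genome
    A = cond_a.total
    B = cond_b.total
    if A <= 0 or B <= 0:
        raise ValueError("empty coverage track")
    psi = pseudocount / np.sqrt(A * B)
    values: dict[str, np.ndarray] = {}
    mask: dict[str, np.ndarray] = {}
    scatter = []
    for chrom, size in genome.sizes.items():
        starts = np.arange(0, size, bin)
        ends = np.minimum(starts + bin, size)
        a = cond_a.integral(chrom, starts, ends)
        b = cond_b.integral(chrom, starts, ends)
        # difference of logs keeps the swap antisymmetry bitwise exact
        fc = np.log2(a / A + psi) - np.log2(b / B + psi)
        values[chrom] = fc
        mask[chrom] = np.zeros(len(fc), dtype=bool)
        scatter.append(pd.DataFrame({"Chromosome": chrom, "Start": starts,
                                     "End": ends, "A": a, "B": b, "FC": fc}))
    track = BinnedTrack(genome, bin, values, mask)
    return track, pd.concat(scatter, ignore_index=True)


def binned_to_step(track: BinnedTrack) -> StepTrack:
    """View a binned track as a piecewise-constant signal (masked bins 0)."""
    segs = {}
    for chrom, size in track.genome.sizes.items():
        starts, ends = track.bin_bounds(chrom)
        edges = np.concatenate([starts, [size]])
        vals = np.where(track.mask[chrom], 0.0, track.values[chrom])
        segs[chrom] = (edges, vals)
    return StepTrack(track.genome, segs)


def border_fold_profile(fc_track: BinnedTrack | StepTrack, partition,
                        flank: int = 500_000, bin: int = 10_000,
                        ) -> dict[str, BorderProfile]:
    """Boundary fold-change curves for each layer of a LayerPartition."""
    step = binned_to_step(fc_track) if isinstance(fc_track, BinnedTrack) \
        else fc_track
    out = {}
    for label, dset in partition.sets.items():
        if label == "iNAD/iLAD" or dset.is_empty:
            continue
        out[label] = border_profile(step, dset, flank=flank, bin=bin)
    return out


def compute_rpkm(genes: pd.DataFrame, library_size: int,
                 threshold: float = 1.0) -> pd.DataFrame:
    """Reads per kilobase of union-exon model per million mapped reads.

    RPKM_g = count_g * 1e9 / (library_size * exon_length_g).  A gene is
    classed "expressed" iff RPKM is strictly greater than the threshold
    (default 1); RPKM exactly 1 is "low".
    ``genes`` needs gene_id / ExonLength / Count columns.
    """
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if (genes["ExonLength"] <= 0).any():
        bad = genes.loc[genes["ExonLength"] <= 0, "gene_id"].tolist()
        raise ValueError(f"zero-length exon models: {bad[:5]}")
    out = genes.copy()
    out["RPKM"] = out["Count"] * 1e9 / (library_size * out["ExonLength"])
    out["Class"] = np.where(out["RPKM"] > threshold, "expressed", "low")
    return out


def genes_in_domains(genes: pd.DataFrame, domains: DomainSet) -> pd.DataFrame:
    """Genes whose midpoint lies inside the domain set (half-open bins: a
    midpoint exactly on a domain start is a member)."""
    if genes.empty:
        return genes.copy()
    mids = ((genes["Start"] + genes["End"]) // 2).to_numpy()
    chroms = genes["Chromosome"].to_numpy(dtype=object)
    inside = domains.contains_points(chroms, mids)
    return genes[inside].reset_index(drop=True)
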