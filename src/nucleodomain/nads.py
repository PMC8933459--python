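"""NAD calling: quantile-threshold segmentation of the DamID ratio track
with a within-chromosome permutation FDR, and replicate intersection.

A candidate domain is a maximal run of consecutive unmasked bins scoring at
or above the min_quant quantile of the genome-wide unmasked score
distribution.  Runs are ranked by their summed score, so a broad domain of
moderately high bins outranks any isolated extreme bin; the null
distribution of run scores comes from permuting bin scores within each
chromosome, which preserves per-chromosome score distributions while
destroying spatial contiguity.  A run's FDR is the mean number of null runs
scoring at least as high, divided by the number of observed runs doing so.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import DomainSet
from .tracks import BinnedTrack


@dataclass
class PeakCall:
    """Called domains plus the per-run report behind them."""

    domains: DomainSet
    report: pd.DataFrame  # all candidate runs with scores and FDR
    threshold: float
    params: dict


def _find_runs(above: np.ndarray, merge_gap: int = 0) -> list[tuple[int, int]]:
    """Maximal [start, end) index runs of True, optionally bridging gaps of
    up to merge_gap False bins between runs."""
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > merge_gap + 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def _run_scores(values: np.ndarray, usable: np.ndarray, threshold: float,
                merge_gap: int) -> tuple[list[tuple[int, int]], np.ndarray]:
    above = usable & (values >= threshold)
    runs = _find_runs(above, merge_gap)
    scores = np.array([values[s:e][usable[s:e]].sum() for s, e in runs])
    return runs, scores


def call_peaks(track: BinnedTrack, fdr_max: float = 0.01,
               min_quant: float = 0.70, n_shuffles: int = 100,
               seed: int | None = None, merge_gap: int = 0,
               label: str = "NAD") -> PeakCall:
    """Call significant domains on a binned ratio track.

    The permutation null is seeded; pass ``seed`` explicitly for
    reproducible pipelines (a default seed of 0 is used and logged in the
    returned params otherwise).
    """
    if seed is None:
        seed = 0
    rng = np.random.default_rng(seed)
    unmasked = track.unmasked_values()
    if len(unmasked) < 100:
        raise ValueError(f"only {len(unmasked)} unmasked bins; need >= 100")
    if np.ptp(unmasked) == 0:
        warnings.warn("degenerate (constant) track: no peaks called")
        return PeakCall(DomainSet.from_intervals([], track.genome, name=label),
                        pd.DataFrame(), float(unmasked[0]),
                        dict(fdr_max=fdr_max, min_quant=min_quant,
                             n_shuffles=n_shuffles, seed=seed))
    threshold = float(np.quantile(unmasked, min_quant))

    observed = []  # (chrom, start_bin, end_bin, run_sum, run_mean)
    for chrom in track.genome.names:
        usable = ~track.mask[chrom]
        runs, scores = _run_scores(track.values[chrom], usable, threshold,
                                   merge_gap)
        for (s, e), sc in zip(runs, scores):
            n_used = int(usable[s:e].sum())
            observed.append((chrom, s, e, float(sc), float(sc) / n_used))
    null_scores = []
    for _ in range(n_shuffles):
        for chrom in track.genome.names:
            usable = ~track.mask[chrom]
            vals = track.values[chrom].copy()
            vals[usable] = rng.permutation(vals[usable])
            _, scores = _run_scores(vals, usable, threshold, merge_gap)
            null_scores.append(scores)
    null = np.sort(np.concatenate(null_scores)) if null_scores else np.array([])

    if not observed:
        return PeakCall(DomainSet.from_intervals([], track.genome, name=label),
                        pd.DataFrame(), threshold,
                        dict(fdr_max=fdr_max, min_quant=min_quant,
                             n_shuffles=n_shuffles, seed=seed))
    obs = pd.DataFrame(observed, columns=["Chromosome", "StartBin", "EndBin",
                                          "RunScore", "MeanScore"])
    obs = obs.sort_values("RunScore", ascending=False).reset_index(drop=True)
    obs_scores = obs["RunScore"].to_numpy()
    # observed count >= s is the rank; null count >= s averaged over shuffles
    n_obs_ge = np.arange(1, len(obs) + 1)
    n_null_ge = len(null) - np.searchsorted(null, obs_scores, side="left")
    fdr = np.clip(n_null_ge / n_shuffles / n_obs_ge, 0.0, 1.0)
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]  # monotone in rank
    obs["FDR"] = fdr

    bs = track.bin_size
    kept = obs[obs["FDR"] < fdr_max]
    intervals = []
    for r in kept.itertuples(index=False):
        size = track.genome.sizes[r.Chromosome]
        intervals.append((r.Chromosome, r.StartBin * bs,
                          min(r.EndBin * bs, size), label, r.MeanScore))
    domains = DomainSet.from_intervals(intervals, track.genome, name=label)
    return PeakCall(domains, obs, threshold,
                    dict(fdr_max=fdr_max, min_quant=min_quant,
                         n_shuffles=n_shuffles, seed=seed, merge_gap=merge_gap))


def intersect_replicates(a: DomainSet, b: DomainSet,
                         min_out: int = 100_000) -> DomainSet:
    """Base-pair intersection of two replicate calls; pieces shorter than
    min_out (default one analysis bin) are dropped."""
    if a.genome != b.genome:
        raise ValueError("mismatched genome contexts")
    out = a.intersect(b, name=a.name or "NAD")
    return out.filter_min_length(min_out).relabel(a.name or "NAD")


def domain_stats(d: DomainSet, proximal_fraction: float = 0.2) -> dict:
    """Summary statistics: count, length distribution, genome coverage,
    per-chromosome coverage, and coverage of the centromere-proximal
    (assembly-start) fifth of each chromosome."""
    genome = d.genome
    if d.is_empty:
        return dict(count=0, min_length=0, median_length=0.0, max_length=0,
                    coverage=0.0, per_chromosome={c: 0.0 for c in genome.names},
                    proximal_coverage={c: 0.0 for c in genome.names})
    merged = d.merge()
    lengths = merged.lengths
    per_chrom_bp = merged.per_chromosome_bp()
    proximal = {}
    for chrom, size in genome.sizes.items():
        seg = DomainSet.from_intervals(
            [(chrom, 0, int(size * proximal_fraction))], genome)
        seg_bp = seg.total_bp
        proximal[chrom] = merged.intersect_bp(seg) / seg_bp if seg_bp else 0.0
    return dict(
        count=len(merged),
        min_length=int(lengths.min()),
        median_length=float(np.median(lengths)),
        max_length=int(lengths.max()),
        coverage=merged.total_bp / genome.total_bp,
        per_chromosome={c: per_chrom_bp[c] / genome.sizes[c]
                        for c in genome.names},
        proximal_coverage=proximal,
    )
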