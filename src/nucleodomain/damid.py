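"""DamID processing: GATC fragment maps, read counting, and the normalized
log2 m6A ratio track.

The nucleolar contact signal is the log2 ratio of library-size-normalized
read counts between the nucleolus-targeted Dam fusion (NoLS) and the
untargeted Dam control, computed per GATC fragment and aggregated into
fixed-width analysis bins (100 kb by default).
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Genome, read_fasta_array
from .tracks import BinnedTrack

# DpnI cleaves GA^TC: fragment boundaries sit 2 bp into each motif.
_CUT_OFFSET = 2


@dataclass
class GatcFragmentMap:
    """Per-chromosome fragments delimited by GATC cleavage points.

    ``cuts[chrom]`` holds the sorted boundary positions including 0 and the
    chromosome length; fragment i on a chromosome is
    [cuts[i], cuts[i+1]) and fragments tile the chromosome exactly.
    """

    genome: Genome
    cuts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self._offsets: dict[str, int] = {}
        off = 0
        for chrom, size in self.genome.sizes.items():
            c = np.asarray(self.cuts[chrom], dtype=np.int64)
            if c[0] != 0 or c[-1] != size or (np.diff(c) <= 0).any():
                raise ValueError(f"invalid fragment boundaries on {chrom}")
            self.cuts[chrom] = c
            self._offsets[chrom] = off
            off += len(c) - 1
        self._n = off

    @property
    def n_fragments(self) -> int:
        return self._n

    def n_fragments_chrom(self, chrom: str) -> int:
        return len(self.cuts[chrom]) - 1

    def offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def flat(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(chroms, starts, ends) over all fragments in genome order."""
        chroms, starts, ends = [], [], []
        for chrom in self.genome.names:
            c = self.cuts[chrom]
            chroms.append(np.full(len(c) - 1, chrom, dtype=object))
            starts.append(c[:-1])
            ends.append(c[1:])
        return (np.concatenate(chroms), np.concatenate(starts),
                np.concatenate(ends))


def build_gatc_fragments(fasta: str | os.PathLike | dict[str, np.ndarray],
                         genome: Genome | None = None) -> GatcFragmentMap:
    """Scan a genome for GATC motifs and return the fragment map.

    The motif is its own reverse complement, so a single forward scan covers
    both strands.  Boundaries are placed at motif start + 2 (the DpnI
    cleavage point between GA and TC).
    """
    if isinstance(fasta, (str, os.PathLike)):
        genome = genome or Genome.from_fasta(fasta)
        seqs = {c: read_fasta_array(fasta, c) for c in genome.names}
    else:
        if genome is None:
            raise ValueError("genome required when passing raw sequences")
        seqs = fasta
    motif = np.frombuffer(b"GATC", dtype=np.uint8)
    cuts: dict[str, np.ndarray] = {}
    for chrom, size in genome.sizes.items():
        seq = seqs[chrom]
        if len(seq) == 0:
            raise ValueError(f"empty sequence for {chrom}")
        if len(seq) >= 4:
            hits = np.flatnonzero(
                (seq[:-3] == motif[0]) & (seq[1:-2] == motif[1])
                & (seq[2:-1] == motif[2]) & (seq[3:] == motif[3]))
        else:
            hits = np.array([], dtype=np.int64)
        bounds = hits + _CUT_OFFSET
        cuts[chrom] = np.unique(np.concatenate([[0], bounds, [size]]))
    return GatcFragmentMap(genome, cuts)


@dataclass
class FragmentCounts:
    """Read counts aligned to a fragment map, plus bookkeeping tallies."""

    fragments: GatcFragmentMap
    counts: np.ndarray
    n_skipped_chrom: int = 0
    n_out_of_bounds: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.fragments.n_fragments:
            raise ValueError("counts length does not match fragment count")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def library_size(self) -> int:
        return int(self.counts.sum())


def count_reads(reads: pd.DataFrame, fragment_map: GatcFragmentMap) -> FragmentCounts:
    """Assign each read to the fragment containing its 5' coordinate.

    ``reads`` needs columns Chromosome and Position (the 5'-most genomic
    coordinate); Strand is accepted but not used for assignment.  Reads on
    chromosomes absent from the map are skipped with a warning; reads out of
    chromosome bounds are rejected.  counted + skipped + rejected equals the
    input read count.
    """
    counts = np.zeros(fragment_map.n_fragments, dtype=np.int64)
    skipped = 0
    oob = 0
    for chrom, sub in reads.groupby("Chromosome", observed=True):
        chrom = str(chrom)
        if chrom not in fragment_map.genome:
            skipped += len(sub)
            continue
        pos = sub["Position"].to_numpy(dtype=np.int64)
        size = fragment_map.genome.sizes[chrom]
        ok = (pos >= 0) & (pos < size)
        oob += int((~ok).sum())
        cuts = fragment_map.cuts[chrom]
        idx = np.searchsorted(cuts, pos[ok], side="right") - 1
        np.add.at(counts, fragment_map.offset(chrom) + idx, 1)
    if skipped:
        warnings.warn(f"{skipped} reads on chromosomes absent from the "
                      "fragment map were skipped")
    return FragmentCounts(fragment_map, counts, skipped, oob)


@dataclass
class FragmentScores:
    """Per-fragment log2 ratio scores with a low-count mask."""

    fragments: GatcFragmentMap
    scores: np.ndarray
    mask: np.ndarray  # True = masked (insufficient counts)


def damid_ratio(nols: FragmentCounts, dam: FragmentCounts,
                pseudocount: float = 1.0, min_total: int = 2) -> FragmentScores:
    """Normalized per-fragment log2 ratio of NoLS over Dam control.

    score_i = log2( ((nols_i + psi) / N_nols) / ((dam_i + psi) / N_dam) )
    with N the library sizes.  Fragments with nols_i + dam_i < min_total
    are masked as uninformative.
    """
    if nols.fragments is not dam.fragments:
        fa, fb = nols.fragments, dam.fragments
        if fa.genome != fb.genome or any(
                not np.array_equal(fa.cuts[c], fb.cuts[c])
                for c in fa.genome.names):
            raise ValueError("mismatched fragment maps")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    n1, n2 = nols.library_size, dam.library_size
    if n1 == 0 or n2 == 0:
        raise ValueError("empty library")
    scores = (np.log2((nols.counts + pseudocount) / n1)
              - np.log2((dam.counts + pseudocount) / n2))
    mask = (nols.counts + dam.counts) < min_total
    return FragmentScores(nols.fragments, scores, mask)


def bin_track(fragment_scores: FragmentScores, bin_size: int = 100_000) -> BinnedTrack:
    """Length-weighted mean of fragment scores per fixed-width bin.

    A fragment straddling a bin edge contributes to each bin in proportion
    to the overlapping base pairs.  Bins with at least half their length
    masked are masked.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    fm = fragment_scores.fragments
    genome = fm.genome
    values: dict[str, np.ndarray] = {}
    mask: dict[str, np.ndarray] = {}
    for chrom, size in genome.sizes.items():
        n_bins = -(-size // bin_size)
        wsum = np.zeros(n_bins)
        w = np.zeros(n_bins)
        masked_bp = np.zeros(n_bins)
        cuts = fm.cuts[chrom]
        starts, ends = cuts[:-1], cuts[1:]
        off = fm.offset(chrom)
        sc = fragment_scores.scores[off:off + len(starts)]
        msk = fragment_scores.mask[off:off + len(starts)]
        b0 = starts // bin_size
        b1 = (ends - 1) // bin_size
        same = b0 == b1
        lens = (ends - starts).astype(float)
        # fragments fully inside one bin (the vast majority)
        np.add.at(masked_bp, b0[same & msk], lens[same & msk])
        ok = same & ~msk
        np.add.at(wsum, b0[ok], sc[ok] * lens[ok])
        np.add.at(w, b0[ok], lens[ok])
        # straddlers: split at bin edges
        for i in np.flatnonzero(~same):
            edges = np.arange(b0[i] + 1, b1[i] + 1) * bin_size
            pieces = np.concatenate([[starts[i]], edges, [ends[i]]])
            plen = np.diff(pieces).astype(float)
            bins = np.arange(b0[i], b1[i] + 1)
            if msk[i]:
                masked_bp[bins] += plen
            else:
                wsum[bins] += sc[i] * plen
                w[bins] += plen
        bin_len = np.minimum((np.arange(n_bins) + 1) * bin_size, size) \
            - np.arange(n_bins) * bin_size
        bmask = (masked_bp >= bin_len / 2) | (w == 0)
        vals = np.zeros(n_bins)
        vals[~bmask] = wsum[~bmask] / w[~bmask]
        values[chrom] = vals
        mask[chrom] = bmask
    return BinnedTrack(genome, bin_size, values, mask)


def track_correlation(a: BinnedTrack, b: BinnedTrack) -> tuple[float, int]:
    """Pearson correlation over jointly unmasked bins; returns (r, n)."""
    if not a.same_binning(b):
        raise ValueError("tracks are not on the same binning")
    xs, ys = [], []
    for chrom in a.genome.names:
        joint = ~a.mask[chrom] & ~b.mask[chrom]
        xs.append(a.values[chrom][joint])
        ys.append(b.values[chrom][joint])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 3:
        raise ValueError(f"only {len(x)} jointly unmasked bins; need >= 3")
    r, _ = stats.pearsonr(x, y)
    return float(r), int(len(x))


def reads_from_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Load aligned-read 5' positions from BED-like tab text.

    Uses the start coordinate for + strand reads and end-1 for - strand
    reads as the 5'-most position.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str})
    out = pd.DataFrame({"Chromosome": df[0], "Position": df[1].astype(np.int64)})
    if df.shape[1] >= 6:
        minus = df[5].astype(str) == "-"
        out.loc[minus, "Position"] = df.loc[minus, 2].astype(np.int64) - 1
        out["Strand"] = df[5]
    return out
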