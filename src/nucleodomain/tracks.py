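"""Signal tracks: piecewise-constant coverage and fixed-width binned tracks.

StepTrack holds an arbitrary bedgraph-style signal and supports exact
length-weighted averaging over any interval via a cumulative integral.
BinnedTrack holds per-bin values on a fixed grid with a missing-data mask;
it backs the DamID log2-ratio track and compartment eigenvector tracks.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome


class StepTrack:
    """Piecewise-constant signal over a genome; 0 where not covered."""

    def __init__(self, genome: Genome,
                 segments: dict[str, tuple[np.ndarray, np.ndarray]]):
        # segments: chrom -> (edges ascending incl. 0 and chrom length,
        #                     values per inter-edge segment)
        self.genome = genome
        self._edges: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, size in genome.sizes.items():
            if chrom in segments:
                edges, values = segments[chrom]
            else:
                edges = np.array([0, size], dtype=np.int64)
                values = np.zeros(1)
            edges = np.asarray(edges, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if edges[0] != 0 or edges[-1] != size or len(values) != len(edges) - 1:
                raise ValueError(f"bad segmentation for {chrom}")
            self._edges[chrom] = edges
            self._values[chrom] = values
            cum = np.concatenate([[0.0], np.cumsum(values * np.diff(edges))])
            self._cum[chrom] = cum

    @classmethod
    def from_intervals(cls, genome: Genome, intervals) -> "StepTrack":
        """Build from (chrom, start, end, value) records; gaps score 0.

        Overlapping input intervals are not supported.
        """
        df = pd.DataFrame(intervals, columns=["Chromosome", "Start", "End", "Value"])
        segs = {}
        for chrom, size in genome.sizes.items():
            sub = df[df["Chromosome"] == chrom].sort_values("Start")
            if (sub["Start"].to_numpy()[1:] < sub["End"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping intervals on {chrom}")
            edges = [0]
            values = []
            for s, e, v in zip(sub["Start"], sub["End"], sub["Value"]):
                s, e = int(s), int(e)
                if e > size or s < 0:
                    raise ValueError(f"interval [{s},{e}) outside {chrom}")
                if s > edges[-1]:
                    values.append(0.0)
                    edges.append(s)
                elif s < edges[-1]:
                    raise ValueError(f"overlapping intervals on {chrom}")
                values.append(float(v))
                edges.append(e)
            if edges[-1] < size:
                values.append(0.0)
                edges.append(size)
            segs[chrom] = (np.array(edges, dtype=np.int64), np.array(values))
        return cls(genome, segs)

    @classmethod
    def read_bedgraph(cls, path: str | os.PathLike, genome: Genome) -> "StepTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["Chromosome", "Start", "End", "Value"],
                         dtype={"Chromosome": str})
        return cls.from_intervals(genome, df.itertuples(index=False, name=None))

    def write_bedgraph(self, path: str | os.PathLike, omit_zero: bool = True) -> None:
        with open(path, "w") as fh:
            for chrom in self.genome.names:
                edges, values = self._edges[chrom], self._values[chrom]
                for s, e, v in zip(edges[:-1], edges[1:], values):
                    if omit_zero and v == 0.0:
                        continue
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")

    def integral(self, chrom: str, a, b) -> np.ndarray | float:
        """Exact integral of the signal over [a, b)."""
        edges, values, cum = self._edges[chrom], self._values[chrom], self._cum[chrom]

        def antideriv(x):
            x = np.clip(np.asarray(x, dtype=float), 0, edges[-1])
            idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(values) - 1)
            return cum[idx] + values[idx] * (x - edges[idx])

        return antideriv(b) - antideriv(a)

    def mean(self, chrom: str, a, b) -> np.ndarray | float:
        """Length-weighted mean over [a, b)."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        return self.integral(chrom, a, b) / (b - a)

    @property
    def total(self) -> float:
        """Genome-wide integral (for coverage tracks: the library size)."""
        return float(sum(c[-1] for c in self._cum.values()))


@dataclass
class BinnedTrack:
    """Fixed-width per-bin values with a missing-data mask (True = masked)."""

    genome: Genome
    bin_size: int
    values: dict[str, np.ndarray] = field(default_factory=dict)
    mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, size in self.genome.sizes.items():
            n = self.n_bins(chrom)
            if chrom not in self.values:
                self.values[chrom] = np.zeros(n)
                self.mask[chrom] = np.ones(n, dtype=bool)
            else:
                self.values[chrom] = np.asarray(self.values[chrom], dtype=float)
                if chrom not in self.mask:
                    self.mask[chrom] = ~np.isfinite(self.values[chrom])
                if len(self.values[chrom]) != n or len(self.mask[chrom]) != n:
                    raise ValueError(f"bin count mismatch on {chrom}")

    def n_bins(self, chrom: str) -> int:
        return -(-self.genome.sizes[chrom] // self.bin_size)

    def bin_bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_bins(chrom)
        starts = np.arange(n, dtype=np.int64) * self.bin_size
        ends = np.minimum(starts + self.bin_size, self.genome.sizes[chrom])
        return starts, ends

    def same_binning(self, other: "BinnedTrack") -> bool:
        return self.genome == other.genome and self.bin_size == other.bin_size

    def unmasked_values(self) -> np.ndarray:
        return np.concatenate([self.values[c][~self.mask[c]] for c in self.genome.names]) \
            if self.genome.names else np.array([])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.genome.names:
            starts, ends = self.bin_bounds(chrom)
            rows.append(pd.DataFrame({
                "Chromosome": chrom, "Start": starts, "End": ends,
                "Value": self.values[chrom], "Masked": self.mask[chrom]}))
        return pd.concat(rows, ignore_index=True)

    def write_bedgraph(self, path: str | os.PathLike) -> None:
        df = self.to_frame()
        df = df[~df["Masked"]]
        df[["Chromosome", "Start", "End", "Value"]].to_csv(
            path, sep="\t", header=False, index=False, float_format="%.6g")

    @classmethod
    def read_bedgraph(cls, path: str | os.PathLike, genome: Genome,
                      bin_size: int) -> "BinnedTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["Chromosome", "Start", "End", "Value"],
                         dtype={"Chromosome": str})
        values: dict[str, np.ndarray] = {}
        mask: dict[str, np.ndarray] = {}
        for chrom, size in genome.sizes.items():
            n = -(-size // bin_size)
            v = np.full(n, np.nan)
            sub = df[df["Chromosome"] == chrom]
            idx = (sub["Start"].to_numpy() // bin_size).astype(int)
            v[idx] = sub["Value"].to_numpy()
            values[chrom] = v
            mask[chrom] = ~np.isfinite(v)
            values[chrom] = np.nan_to_num(v)
        return cls(genome, bin_size, values, mask)
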