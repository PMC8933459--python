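"""Labelled genomic interval sets and base-pair-level set algebra.

DomainSet is the package's container for NADs, LADs, genome layers and
cell-type-specific domain sets: sorted, non-overlapping (within a label),
half-open intervals tied to a genome context.  The set operations
(intersection, difference, merge, complement) are delegated to pyranges and
are exact at base-pair level.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr

from .genome import Genome

_COLS = ["Chromosome", "Start", "End", "Label", "Score"]


def _empty_df() -> pd.DataFrame:
    return pd.DataFrame({
        "Chromosome": pd.Series(dtype=str),
        "Start": pd.Series(dtype=np.int64),
        "End": pd.Series(dtype=np.int64),
        "Label": pd.Series(dtype=str),
        "Score": pd.Series(dtype=float),
    })


@dataclass
class DomainSet:
    """Sorted, labelled, half-open genomic intervals with a genome context."""

    df: pd.DataFrame
    genome: Genome
    name: str = ""

    def __post_init__(self) -> None:
        df = self.df.copy()
        if df.empty:
            df = _empty_df()
        if "Label" not in df.columns:
            df["Label"] = self.name or "."
        if "Score" not in df.columns:
            df["Score"] = 0.0
        df = df[_COLS].astype({"Start": np.int64, "End": np.int64, "Score": float})
        df["Chromosome"] = df["Chromosome"].astype(str)
        df = df.sort_values(["Chromosome", "Start", "End"], kind="stable").reset_index(drop=True)
        self._validate(df)
        self.df = df

    def _validate(self, df: pd.DataFrame) -> None:
        if (df["Start"] >= df["End"]).any():
            raise ValueError("intervals must satisfy start < end")
        for chrom, sub in df.groupby("Chromosome", observed=True):
            if chrom not in self.genome:
                raise ValueError(f"chromosome {chrom!r} not in genome context")
            if int(sub["End"].max()) > self.genome.sizes[chrom]:
                raise ValueError(f"interval beyond end of {chrom}")
            for _, lab_sub in sub.groupby("Label", observed=True):
                starts = lab_sub["Start"].to_numpy()
                ends = lab_sub["End"].to_numpy()
                if (starts[1:] < ends[:-1]).any():
                    raise ValueError(f"overlapping intervals within label on {chrom}")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_intervals(cls, intervals, genome: Genome, name: str = "") -> "DomainSet":
        """Build from an iterable of (chrom, start, end[, label[, score]])."""
        rows = []
        for iv in intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            label = iv[3] if len(iv) > 3 else (name or ".")
            score = float(iv[4]) if len(iv) > 4 else 0.0
            rows.append((chrom, start, end, label, score))
        df = pd.DataFrame(rows, columns=_COLS) if rows else _empty_df()
        return cls(df, genome, name=name)

    @classmethod
    def read_bed(cls, path: str | os.PathLike, genome: Genome, name: str = "") -> "DomainSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["Chromosome", "Start", "End"],
                         dtype={0: str})
        try:
            full = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
            if full.shape[1] >= 4:
                df["Label"] = full[3].astype(str)
            if full.shape[1] >= 5:
                df["Score"] = pd.to_numeric(full[4], errors="coerce").fillna(0.0)
        except pd.errors.EmptyDataError:
            pass
        return cls(df, genome, name=name)

    def write_bed(self, path: str | os.PathLike) -> None:
        out = self.df.copy()
        out["Score"] = np.round(out["Score"] * 100).astype(int)
        out["Strand"] = "."
        out.to_csv(path, sep="\t", header=False, index=False)

    # -- basic properties ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def is_empty(self) -> bool:
        return self.df.empty

    @property
    def total_bp(self) -> int:
        """Covered base pairs (intervals merged across labels first)."""
        if self.is_empty:
            return 0
        return int((self.merge().df["End"] - self.merge().df["Start"]).sum())

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["End"] - self.df["Start"]).to_numpy()

    def coverage_fraction(self) -> float:
        return self.total_bp / self.genome.total_bp

    def per_chromosome_bp(self) -> dict[str, int]:
        m = self.merge().df
        out = {c: 0 for c in self.genome.names}
        for chrom, sub in m.groupby("Chromosome", observed=True):
            out[str(chrom)] = int((sub["End"] - sub["Start"]).sum())
        return out

    # -- set algebra --------------------------------------------------------

    def _pr(self) -> pr.PyRanges:
        return pr.PyRanges(self.df[["Chromosome", "Start", "End"]].copy())

    def _wrap(self, ranges: pr.PyRanges, name: str) -> "DomainSet":
        df = ranges.df if len(ranges) else _empty_df()
        df = df[["Chromosome", "Start", "End"]].copy() if len(df) else _empty_df()
        return DomainSet(df, self.genome, name=name)

    def _check_context(self, other: "DomainSet") -> None:
        if self.genome != other.genome:
            raise ValueError("mismatched genome contexts")

    def merge(self) -> "DomainSet":
        """Union of all intervals regardless of label."""
        if self.is_empty:
            return DomainSet(_empty_df(), self.genome, name=self.name)
        return self._wrap(self._pr().merge(), self.name)

    def intersect(self, other: "DomainSet", name: str = "") -> "DomainSet":
        self._check_context(other)
        if self.is_empty or other.is_empty:
            return DomainSet(_empty_df(), self.genome, name=name)
        return self._wrap(self._pr().merge().intersect(other._pr().merge()), name)

    def subtract(self, other: "DomainSet", name: str = "") -> "DomainSet":
        self._check_context(other)
        if self.is_empty:
            return DomainSet(_empty_df(), self.genome, name=name)
        if other.is_empty:
            out = self.merge()
            out.name = name
            return out
        return self._wrap(self._pr().merge().subtract(other._pr().merge()), name)

    def complement(self, name: str = "") -> "DomainSet":
        """Genome-wide complement of the covered base pairs."""
        covered = self.merge().df
        rows = []
        for chrom, size in self.genome.sizes.items():
            sub = covered[covered["Chromosome"] == chrom]
            pos = 0
            for start, end in zip(sub["Start"], sub["End"]):
                if start > pos:
                    rows.append((chrom, pos, start))
                pos = max(pos, int(end))
            if pos < size:
                rows.append((chrom, pos, size))
        df = pd.DataFrame(rows, columns=["Chromosome", "Start", "End"]) if rows else _empty_df()
        return DomainSet(df, self.genome, name=name)

    def filter_min_length(self, min_len: int) -> "DomainSet":
        return DomainSet(self.df[(self.df["End"] - self.df["Start"]) >= min_len],
                         self.genome, name=self.name)

    def relabel(self, label: str) -> "DomainSet":
        df = self.df.copy()
        df["Label"] = label
        return DomainSet(df, self.genome, name=label)

    def intersect_bp(self, other: "DomainSet") -> int:
        """Shared base pairs with another set."""
        return self.intersect(other).total_bp

    def jaccard(self, other: "DomainSet") -> float:
        """bp-level Jaccard index between the covered regions of two sets."""
        inter = self.intersect_bp(other)
        union = self.total_bp + other.total_bp - inter
        return inter / union if union else float("nan")

    def contains_points(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Boolean membership of (chrom, pos) points in the covered region."""
        out = np.zeros(len(positions), dtype=bool)
        m = self.merge().df
        for chrom, sub in m.groupby("Chromosome", observed=True):
            sel = chroms == chrom
            if not sel.any():
                continue
            starts = sub["Start"].to_numpy()
            ends = sub["End"].to_numpy()
            idx = np.searchsorted(starts, positions[sel], side="right") - 1
            ok = (idx >= 0) & (positions[sel] < ends[np.clip(idx, 0, len(ends) - 1)])
            out[np.flatnonzero(sel)] = ok
        return out
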