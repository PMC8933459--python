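"""Genome context: ordered chromosome sizes and FASTA/chrom.sizes I/O.

All coordinates in this package are 0-based, half-open, in base pairs.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from pyfaidx import Fasta


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome names and lengths."""

    sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return list(self.sizes)

    @property
    def total_bp(self) -> int:
        return sum(self.sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __len__(self) -> int:
        return len(self.sizes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and dict(self.sizes) == dict(other.sizes)

    @classmethod
    def from_chrom_sizes(cls, path: str | os.PathLike) -> "Genome":
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                name, length = line.split("\t")[:2]
                sizes[name] = int(length)
        return cls(sizes)

    def to_chrom_sizes(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for name, length in self.sizes.items():
                fh.write(f"{name}\t{length}\n")

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Genome":
        fa = Fasta(str(path))
        return cls({name: len(fa[name]) for name in fa.keys()})


def write_fasta(path: str | os.PathLike, sequences: dict[str, str | bytes],
                width: int = 80) -> None:
    """Write sequences to FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            if isinstance(seq, (bytes, bytearray)):
                seq = seq.decode("ascii")
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width])
                fh.write("\n")


def read_fasta_array(path: str | os.PathLike, chrom: str) -> np.ndarray:
    """Load one chromosome as an upper-case uint8 array of ASCII codes."""
    fa = Fasta(str(path))
    seq = str(fa[chrom][:]).upper()
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
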