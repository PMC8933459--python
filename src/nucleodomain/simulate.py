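"""Synthetic genomes and assay data with planted nucleolar architecture.

This module generates everything the analysis consumes — a GATC-bearing
genome with an rRNA gene unit appended to the last chromosome, DamID
fragment counts, distance-decaying Hi-C pairs with boosted rDNA-anchor
contacts, ChIP coverage tracks, and gene expression counts — from a planted
domain layout, so that every downstream stage can be verified against known
truth.

The generative assumptions mirror the structure of the real assays:

* DamID counts are negative binomial with mean proportional to GATC-fragment
  length; the nucleolar (NoLS) sample's rate is multiplied by a fold
  enrichment inside planted NADs.
* Hi-C cis pair separations follow a power law P(s) ~ s^-alpha; pairs with
  one end in the rDNA unit preferentially target planted NADs and the
  centromere-proximal fifth of each chromosome; an alternating A/B
  checkerboard boosts same-compartment pairs.
* ChIP signal is gamma-distributed per 50-bp bin around a layer-specific
  mean; expression counts are Poisson around a layer-specific RPKM.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genome import Genome, write_fasta
from .intervals import DomainSet

LAYER_LABELS = ("NAD-only", "NAD/LAD", "LAD-only", "none")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GATC = np.frombuffer(b"GATC", dtype=np.uint8)


def _default_chip_means() -> dict[str, dict[str, float]]:
    return {
        "H3K9me2": {"NAD-only": 2.0, "NAD/LAD": 4.0, "LAD-only": 2.0, "none": 1.0},
        "H3K9me3": {"NAD-only": 3.0, "NAD/LAD": 3.0, "LAD-only": 2.0, "none": 1.0},
    }


def _default_expr_means() -> dict[str, float]:
    return {"NAD-only": 0.2, "NAD/LAD": 0.2, "LAD-only": 0.5, "none": 5.0}


def design_paired_layouts(chrom_names: tuple[str, ...] = ("chr1", "chr2", "chr3"),
                          bin_size: int = 100_000,
                          ) -> tuple[list[tuple], list[tuple]]:
    """Deterministic two-cell-type domain architecture.

    Builds matched embryonic-stem-cell-like (cell 1) and neural-progenitor-
    like (cell 2) layouts whose designed statistics echo the headline
    organisation of mouse NADs: ~53% of NAD bp shared with LADs, ~40% of LAD
    bp shared with NADs, and 78% of cell-1-specific NAD-only bp landing in
    neither compartment of cell 2.

    Returns two layout lists of (chrom, start, end, label).
    """
    # (cell1 label, [(cell2 label, bins), ...], total bins)
    groups: dict[str, list] = {
        "shared": [("NAD/LAD", [("NAD/LAD", 7)], 7)] * 8,
        "lads": [("LAD-only", [("LAD-only", 7)], 7)] * 12,
        "c1nads": ([("NAD-only", [("LAD-only", 5)], 5)] * 2
                   + [("NAD-only", [("LAD-only", 1), ("none", 4)], 5)]
                   + [("NAD-only", [("none", 5)], 5)] * 7),
        "c2nads": [("none", [("NAD-only", 5)], 5)] * 4,
    }
    # round-robin interleave so every chromosome carries every domain class
    order = []
    keys = list(groups)
    while any(groups.values()):
        for k in keys:
            if groups[k]:
                order.append(groups[k].pop(0))

    gap = 15  # bins between domains
    layout1, layout2 = [], []
    cursors = {c: 5 for c in chrom_names}
    for i, (lab1, lab2_parts, n_bins) in enumerate(order):
        chrom = chrom_names[i % len(chrom_names)]
        start = cursors[chrom] * bin_size
        if lab1 != "none":
            layout1.append((chrom, start, start + n_bins * bin_size, lab1))
        pos = start
        for lab2, nb in lab2_parts:
            if lab2 != "none":
                layout2.append((chrom, pos, pos + nb * bin_size, lab2))
            pos += nb * bin_size
        cursors[chrom] += n_bins + gap
    return layout1, layout2


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults define the desk-scale
    conditions used throughout the test-suite (3 x 30-Mb chromosomes,
    100-kb analysis bins, 2M DamID reads per sample, 4-fold nucleolar
    enrichment)."""

    chrom_lengths: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 30_000_000), ("chr2", 30_000_000),
                                 ("chr3", 30_000_000)])
    gatc_spacing_mean: int = 500
    rdna_unit_length: int = 45_000
    domain_layout: list[tuple] = field(
        default_factory=lambda: design_paired_layouts()[0])
    bin_size: int = 100_000
    compartment_period: int = 2_000_000
    damid_depth: int = 2_000_000
    damid_enrichment: float = 4.0
    damid_dispersion: float = 0.1
    hic_n_pairs: int = 1_000_000
    hic_decay_alpha: float = 1.0
    hic_rdna_boost: float = 5.0
    hic_quintile1_boost: float = 3.0
    hic_compartment_boost: float = 2.0
    hic_rdna_fraction: float = 0.1
    hic_min_separation: int = 1_000
    chip_state_means: dict = field(default_factory=_default_chip_means)
    chip_bin: int = 50
    chip_gamma_shape: float = 5.0
    expr_state_means: dict = field(default_factory=_default_expr_means)
    rna_library_size: int = 10_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.chrom_lengths = [(str(n), int(l)) for n, l in self.chrom_lengths]
        self.domain_layout = [tuple(iv) for iv in self.domain_layout]
        self.validate()

    def validate(self) -> None:
        sizes = dict(self.chrom_lengths)
        if not sizes:
            raise ValueError("at least one chromosome required")
        for name, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        last_name, last_len = self.chrom_lengths[-1]
        if last_len < self.rdna_unit_length:
            raise ValueError(
                f"last chromosome {last_name} ({last_len} bp) is shorter than "
                f"the rDNA unit ({self.rdna_unit_length} bp)")
        for val, what in [(self.gatc_spacing_mean, "gatc_spacing_mean"),
                          (self.rdna_unit_length, "rdna_unit_length"),
                          (self.bin_size, "bin_size"),
                          (self.compartment_period, "compartment_period")]:
            if val <= 0:
                raise ValueError(f"{what} must be positive")
        for val, what in [(self.damid_enrichment, "damid_enrichment"),
                          (self.hic_rdna_boost, "hic_rdna_boost"),
                          (self.hic_quintile1_boost, "hic_quintile1_boost"),
                          (self.hic_compartment_boost, "hic_compartment_boost")]:
            if val <= 0:
                raise ValueError(f"{what} (a fold) must be > 0")
        by_chrom: dict[str, list] = {}
        for chrom, start, end, label in self.domain_layout:
            if label not in LAYER_LABELS:
                raise ValueError(f"unknown layout label {label!r}")
            if chrom not in sizes:
                raise ValueError(f"layout chromosome {chrom!r} not in genome")
            if not (0 <= start < end <= sizes[chrom]):
                raise ValueError(f"layout interval [{start},{end}) outside {chrom}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping layout intervals on {chrom}")

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class SimTruth:
    """Planted architecture: the ground truth downstream calls are scored
    against."""

    genome: Genome                       # rDNA-extended sizes
    config: SimConfig
    rdna_interval: tuple[str, int, int]
    nad_truth: DomainSet = field(init=False)
    lad_truth: DomainSet = field(init=False)

    def __post_init__(self) -> None:
        chrom, start, end = self.rdna_interval
        if end != self.genome.sizes[chrom]:
            raise ValueError("rDNA interval must terminate its chromosome")
        layout = self.config.domain_layout
        self.nad_truth = DomainSet.from_intervals(
            [iv for iv in layout if iv[3] in ("NAD-only", "NAD/LAD")],
            self.genome, name="NAD")
        self.lad_truth = DomainSet.from_intervals(
            [iv for iv in layout if iv[3] in ("NAD/LAD", "LAD-only")],
            self.genome, name="LAD")

    def layer(self, label: str) -> DomainSet:
        """Planted intervals of one layer label."""
        return DomainSet.from_intervals(
            [iv for iv in self.config.domain_layout if iv[3] == label],
            self.genome, name=label)

    def layer_labels_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Layer label of each position ('none' outside the layout)."""
        out = np.full(len(positions), "none", dtype=object)
        for c, start, end, label in self.config.domain_layout:
            if c == chrom:
                out[(positions >= start) & (positions < end)] = label
        return out

    def compartment_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Checkerboard compartment label ('A' or 'B') of positions."""
        blocks = (np.asarray(positions) // self.config.compartment_period) % 2
        return np.where(blocks == 0, "A", "B")

    def compartment_truth(self, bin_size: int | None = None) -> dict[str, np.ndarray]:
        """Per-bin A/B labels tiling the genome."""
        bs = bin_size or self.config.bin_size
        out = {}
        for chrom, size in self.genome.sizes.items():
            starts = np.arange(0, size, bs)
            out[chrom] = self.compartment_at(chrom, starts)
        return out


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _random_sequence_without_gatc(rng: np.random.Generator, length: int) -> np.ndarray:
    seq = _BASES[rng.integers(0, 4, size=length)]
    # disrupt chance GATCs; replacing the C with A cannot create a new motif
    hits = np.flatnonzero(
        (seq[:-3] == _GATC[0]) & (seq[1:-2] == _GATC[1])
        & (seq[2:-1] == _GATC[2]) & (seq[3:] == _GATC[3]))
    seq[hits + 3] = _BASES[0]
    return seq


def _plant_gatc(rng: np.random.Generator, seq: np.ndarray, spacing_mean: int) -> None:
    """Overwrite GATC motifs at renewal-process positions (mean gap =
    spacing_mean, minimum 4 bp so motifs never overlap)."""
    length = len(seq)
    if spacing_mean <= 4:
        raise ValueError("gatc_spacing_mean must exceed the motif length (4)")
    n_draw = int(length / spacing_mean * 1.5) + 10
    pos = []
    cursor = 0.0
    while True:
        gaps = 4.0 + rng.exponential(spacing_mean - 4, size=n_draw)
        starts = cursor + np.cumsum(gaps)
        keep = starts <= length - 4
        pos.append(starts[keep].astype(np.int64))
        if not keep.all():
            break
        cursor = float(starts[-1])
    for p in np.concatenate(pos):
        seq[p:p + 4] = _GATC


def simulate_genome(config: SimConfig, outdir: str | os.PathLike) -> SimTruth:
    """Write genome.fa / genome.chrom.sizes and return the planted truth.

    The last chromosome is extended by one rDNA unit; GATC motifs are planted
    at approximately config.gatc_spacing_mean spacing. Deterministic under
    config.seed.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sequences: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    last = config.chrom_lengths[-1][0]
    for name, length in config.chrom_lengths:
        total = length + (config.rdna_unit_length if name == last else 0)
        seq = _random_sequence_without_gatc(rng, total)
        _plant_gatc(rng, seq, config.gatc_spacing_mean)
        sequences[name] = seq
        sizes[name] = total
    genome = Genome(sizes)
    rdna_interval = (last, config.chrom_lengths[-1][1], sizes[last])

    write_fasta(os.path.join(outdir, "genome.fa"),
                {n: s.tobytes() for n, s in sequences.items()})
    genome.to_chrom_sizes(os.path.join(outdir, "genome.chrom.sizes"))
    truth = SimTruth(genome, config, rdna_interval)
    truth.nad_truth.write_bed(os.path.join(outdir, "truth_nads.bed"))
    truth.lad_truth.write_bed(os.path.join(outdir, "truth_lads.bed"))
    return truth


# ---------------------------------------------------------------------------
# DamID
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson limit at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_damid(truth: SimTruth, fragments, seed: int | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Fragment-level counts for the nucleolar (NoLS) and control (Dam)
    samples.

    Returns (nols_counts, dam_counts) aligned to ``fragments`` (a
    GatcFragmentMap).  The control mean is proportional to fragment length;
    the NoLS mean is additionally multiplied by config.damid_enrichment for
    fragments whose midpoint lies inside a planted NAD, then rescaled so both
    totals match config.damid_depth in expectation.
    """
    cfg = truth.config
    if fragments.n_fragments == 0:
        raise ValueError("empty fragment map")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    chroms, starts, ends = fragments.flat()
    lengths = (ends - starts).astype(float)
    mids = (starts + ends) // 2
    in_nad = truth.nad_truth.contains_points(chroms, mids)

    dam_mean = cfg.damid_depth * lengths / lengths.sum()
    w = lengths * np.where(in_nad, cfg.damid_enrichment, 1.0)
    nols_mean = cfg.damid_depth * w / w.sum()
    dam = _nb_draw(rng, dam_mean, cfg.damid_dispersion)
    nols = _nb_draw(rng, nols_mean, cfg.damid_dispersion)
    return nols, dam


# ---------------------------------------------------------------------------
# Hi-C pairs
# ---------------------------------------------------------------------------

def _sample_power_law(rng: np.random.Generator, n: int, alpha: float,
                      s_min: float, s_max: np.ndarray) -> np.ndarray:
    """Truncated power-law separations, density ~ s^-alpha on [s_min, s_max]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return s_min * (s_max / s_min) ** u
    a = 1.0 - alpha
    return (s_min ** a + u * (s_max ** a - s_min ** a)) ** (1.0 / a)


def _weighted_segments(truth: SimTruth) -> pd.DataFrame:
    """Per-bp sampling weight segments for the non-rDNA end of anchored pairs."""
    cfg = truth.config
    rows = []
    for chrom, size in truth.genome.sizes.items():
        breaks = {0, size, size // 5}
        for c, s, e, lab in cfg.domain_layout:
            if c == chrom:
                breaks.update((s, e))
        if chrom == truth.rdna_interval[0]:
            breaks.add(truth.rdna_interval[1])
        edges = np.array(sorted(breaks))
        for s, e in zip(edges[:-1], edges[1:]):
            mid = np.array([(s + e) // 2])
            if chrom == truth.rdna_interval[0] and s >= truth.rdna_interval[1]:
                continue  # never target the rDNA unit itself
            w = 1.0
            if truth.nad_truth.contains_points(np.array([chrom], dtype=object),
                                               mid)[0]:
                w *= cfg.hic_rdna_boost
            if e <= size // 5:
                w *= cfg.hic_quintile1_boost
            rows.append((chrom, int(s), int(e), w))
    return pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "Weight"])


def simulate_hic_pairs(truth: SimTruth, path: str | os.PathLike,
                       seed: int | None = None) -> pd.DataFrame:
    """Write a 7-column pairs file and return it as a DataFrame.

    A configured fraction of pairs is anchored in the rDNA unit with the
    other end drawn genome-wide under NAD and centromere-proximal (first
    fifth) boosts; the remainder are cis pairs with power-law separations and
    a same-compartment checkerboard boost.
    """
    cfg = truth.config
    if cfg.hic_n_pairs <= 0:
        raise ValueError("hic_n_pairs must be positive")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genome = truth.genome
    names = np.array(genome.names, dtype=object)
    sizes = np.array([genome.sizes[c] for c in names], dtype=float)

    n_rdna = int(round(cfg.hic_n_pairs * cfg.hic_rdna_fraction))
    n_cis = cfg.hic_n_pairs - n_rdna

    # --- generic cis pairs with distance decay + compartment checkerboard
    chrom_idx = rng.choice(len(names), size=n_cis, p=sizes / sizes.sum())
    c1 = names[chrom_idx]
    L = sizes[chrom_idx]
    pos1 = np.empty(n_cis, dtype=np.int64)
    pos2 = np.empty(n_cis, dtype=np.int64)
    todo = np.arange(n_cis)
    while len(todo):
        p1 = (rng.random(len(todo)) * L[todo]).astype(np.int64)
        s = _sample_power_law(rng, len(todo), cfg.hic_decay_alpha,
                              cfg.hic_min_separation, L[todo] / 2.0)
        sign = np.where(rng.random(len(todo)) < 0.5, 1, -1)
        p2 = p1 + (sign * s).astype(np.int64)
        ok = (p2 >= 0) & (p2 < L[todo])
        if cfg.hic_compartment_boost != 1.0:
            blocks1 = (p1 // cfg.compartment_period) % 2
            blocks2 = (np.clip(p2, 0, None) // cfg.compartment_period) % 2
            w = np.where(blocks1 == blocks2, cfg.hic_compartment_boost, 1.0)
            ok &= rng.random(len(todo)) < w / cfg.hic_compartment_boost
        pos1[todo[ok]] = p1[ok]
        pos2[todo[ok]] = p2[ok]
        todo = todo[~ok]
    cis = pd.DataFrame({"chrom1": c1, "pos1": pos1, "chrom2": c1, "pos2": pos2})

    # --- rDNA-anchored pairs
    if n_rdna:
        rchrom, rstart, rend = truth.rdna_interval
        anchor = rng.integers(rstart, rend, size=n_rdna)
        segs = _weighted_segments(truth)
        seg_w = segs["Weight"].to_numpy() * (segs["End"] - segs["Start"]).to_numpy()
        pick = rng.choice(len(segs), size=n_rdna, p=seg_w / seg_w.sum())
        s_arr = segs["Start"].to_numpy()[pick]
        e_arr = segs["End"].to_numpy()[pick]
        tpos = s_arr + (rng.random(n_rdna) * (e_arr - s_arr)).astype(np.int64)
        tchrom = segs["Chromosome"].to_numpy()[pick]
        rd = pd.DataFrame({"chrom1": rchrom, "pos1": anchor,
                           "chrom2": tchrom, "pos2": tpos})
        pairs = pd.concat([cis, rd], ignore_index=True)
    else:
        pairs = cis

    pairs.insert(0, "readID", [f"r{i}" for i in range(len(pairs))])
    pairs["strand1"] = np.where(rng.random(len(pairs)) < 0.5, "+", "-")
    pairs["strand2"] = np.where(rng.random(len(pairs)) < 0.5, "+", "-")
    pairs.to_csv(path, sep="\t", header=False, index=False)
    return pairs


# ---------------------------------------------------------------------------
# ChIP tracks
# ---------------------------------------------------------------------------

def simulate_chip_tracks(truth: SimTruth, outdir: str | os.PathLike,
                         marks: list[str] | None = None,
                         seed: int | None = None) -> dict[str, str]:
    """One bedgraph per mark with gamma-distributed 50-bp-bin signal around
    the layer-specific mean. Returns mark -> path."""
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    os.makedirs(outdir, exist_ok=True)
    marks = marks or list(cfg.chip_state_means)
    out: dict[str, str] = {}
    for mark in marks:
        if mark not in cfg.chip_state_means:
            raise KeyError(f"no state means configured for mark {mark!r}")
        means = cfg.chip_state_means[mark]
        for lab in LAYER_LABELS:
            if lab not in means:
                raise KeyError(f"mark {mark!r} missing mean for layer {lab!r}")
        path = os.path.join(outdir, f"{mark}.bedgraph")
        with open(path, "w") as fh:
            for chrom, size in truth.genome.sizes.items():
                starts = np.arange(0, size, cfg.chip_bin)
                ends = np.minimum(starts + cfg.chip_bin, size)
                labels = truth.layer_labels_at(chrom, (starts + ends) // 2)
                mu = np.array([means[l] for l in labels])
                vals = np.zeros(len(mu))
                pos = mu > 0
                vals[pos] = rng.gamma(cfg.chip_gamma_shape,
                                      mu[pos] / cfg.chip_gamma_shape)
                block = pd.DataFrame({"c": chrom, "s": starts, "e": ends,
                                      "v": np.round(vals, 4)})
                block.to_csv(fh, sep="\t", header=False, index=False)
        out[mark] = path
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(truth: SimTruth, n_genes: int,
                        seed: int | None = None,
                        ) -> tuple[pd.DataFrame, int]:
    """Uniformly placed single-exon genes with Poisson counts targeting the
    layer-specific mean RPKM. Returns (gene table, library size)."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genome = truth.genome
    names = np.array(genome.names, dtype=object)
    sizes = np.array([genome.sizes[c] for c in names], dtype=float)
    chrom_idx = rng.choice(len(names), size=n_genes, p=sizes / sizes.sum())
    lengths = rng.integers(1_000, 10_000, size=n_genes)
    starts = (rng.random(n_genes) * (sizes[chrom_idx] - lengths)).astype(np.int64)
    chroms = names[chrom_idx]
    mids = starts + lengths // 2
    labels = np.full(n_genes, "none", dtype=object)
    for chrom in genome.names:
        sel = chroms == chrom
        labels[sel] = truth.layer_labels_at(chrom, mids[sel])
    mean_rpkm = np.array([cfg.expr_state_means[l] for l in labels])
    expected = mean_rpkm * lengths * cfg.rna_library_size / 1e9
    counts = rng.poisson(expected)
    genes = pd.DataFrame({
        "gene_id": [f"gene{i}" for i in range(n_genes)],
        "Chromosome": chroms,
        "Start": starts,
        "End": starts + lengths,
        "Strand": np.where(rng.random(n_genes) < 0.5, "+", "-"),
        "ExonLength": lengths,
        "Count": counts,
        "TruthLabel": labels,
    })
    return genes, int(cfg.rna_library_size)


def write_gtf(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write gene/exon records (1-based closed coordinates, GTF convention)."""
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            attrs = f'gene_id "{g.gene_id}";'
            for feat in ("gene", "exon"):
                fh.write(f"{g.Chromosome}\tsim\t{feat}\t{g.Start + 1}\t{g.End}\t."
                         f"\t{g.Strand}\t.\t{attrs}\n")


def write_counts(genes: pd.DataFrame, library_size: int,
                 path: str | os.PathLike) -> None:
    genes[["gene_id", "ExonLength", "Count"]].to_csv(path, sep="\t", index=False)
    with open(str(path) + ".libsize", "w") as fh:
        fh.write(f"{library_size}\n")
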