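"""rDNA-anchored Hi-C contact extraction, Knight-Ruiz balancing, replicate
intersection and positional distributions.

The reference carries one rRNA gene unit appended to the end of one
chromosome; a usable contact is a read pair with exactly one end inside
that unit.  The non-rDNA end is binned (5 kb by default), counts are
accumulated per bin, and scores are the raw counts times per-bin balancing
weights from KR scaling of the cis contact matrix.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import Genome, write_fasta
from .intervals import DomainSet
from pyfaidx import Fasta


@dataclass(frozen=True)
class GenomeIndex:
    """Genome context plus the coordinates of the appended rRNA gene unit."""

    genome: Genome
    rdna_interval: tuple[str, int, int]

    def __post_init__(self) -> None:
        chrom, start, end = self.rdna_interval
        if chrom not in self.genome:
            raise ValueError(f"rDNA chromosome {chrom!r} not in genome")
        if end != self.genome.sizes[chrom] or not 0 <= start < end:
            raise ValueError("rDNA interval must be the terminal segment of "
                             "its chromosome")

    def in_rdna(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        chrom, start, end = self.rdna_interval
        return (np.asarray(chroms) == chrom) & (positions >= start) & (positions < end)


def append_rdna(genome_fasta: str | os.PathLike, rdna_fasta: str | os.PathLike,
                target_chrom: str, out_fasta: str | os.PathLike,
                force: bool = False) -> GenomeIndex:
    """Concatenate one rRNA gene unit to the end of a chromosome.

    All pre-existing coordinates are unchanged; the new unit occupies
    [old_length, old_length + unit_length) on the target chromosome.
    Refuses to append twice (unit already terminal) unless ``force``.
    """
    fa = Fasta(str(genome_fasta))
    if target_chrom not in fa.keys():
        raise ValueError(f"target chromosome {target_chrom!r} not found")
    unit_fa = Fasta(str(rdna_fasta))
    unit = "".join(str(unit_fa[k][:]) for k in unit_fa.keys())
    if not unit:
        raise ValueError("rDNA unit sequence is empty")
    target_seq = str(fa[target_chrom][:])
    if target_seq.endswith(unit) and not force:
        raise ValueError("rDNA unit already terminal on target chromosome "
                         "(use force=True to append anyway)")
    sequences = {}
    sizes = {}
    for name in fa.keys():
        seq = str(fa[name][:])
        if name == target_chrom:
            seq = seq + unit
        sequences[name] = seq
        sizes[name] = len(seq)
    write_fasta(out_fasta, sequences)
    old_len = len(target_seq)
    return GenomeIndex(Genome(sizes), (target_chrom, old_len, old_len + len(unit)))


# ---------------------------------------------------------------------------
# Knight-Ruiz balancing
# ---------------------------------------------------------------------------

@dataclass
class KRResult:
    scale: np.ndarray          # per-bin scaling; NaN at masked bins
    mask: np.ndarray           # True = masked (sparse row)
    converged: bool
    method: str                # "KR" or "sinkhorn"

    def balanced(self, matrix) -> np.ndarray:
        """diag(x) . A . diag(x) on the unmasked submatrix (dense)."""
        A = np.asarray(matrix.todense() if sp.issparse(matrix) else matrix,
                       dtype=float)
        keep = ~self.mask
        x = self.scale[keep]
        return A[np.ix_(keep, keep)] * np.outer(x, x)


def _bnewt(A, tol: float = 1e-8, delta: float = 0.1, Delta: float = 3.0,
           max_outer: int = 50) -> tuple[np.ndarray, bool]:
    """Knight-Ruiz inner-outer Newton iteration for matrix balancing.

    Finds x > 0 with diag(x) A diag(x) doubly stochastic. A must be
    symmetric non-negative with total support.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol ** 2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rold = rho_km1
    i = 0
    while rout > rt:
        i += 1
        if i > max_outer:
            return x, False
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            if k > 10 * n:
                return x, False
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                neg = ap < 0
                if not neg.any():
                    break
                gamma = ((delta - y[neg]) / ap[neg]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                big = ynew > Delta
                gamma = ((Delta - y[big]) / ap[big]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        eta = g * rat
        if g * eta ** 2 > 0.1:
            eta = max(eta, g * eta ** 2)
        eta = max(min(eta, etamax), stop_tol / np.sqrt(rout))
    return x, True


def _sinkhorn(A, tol: float = 1e-10, max_iter: int = 50_000) -> tuple[np.ndarray, bool]:
    """Iterative proportional scaling fallback (symmetric variant)."""
    n = A.shape[0]
    x = np.ones(n)
    for _ in range(max_iter):
        r = x * (A @ x)
        x = x / np.sqrt(r)
        err = np.abs(x * (A @ x) - 1.0).max()
        if err < tol:
            return x, True
    return x, False


def kr_balance(matrix, min_nonzero_frac: float = 0.10,
               tol: float = 1e-8, symmetry_rtol: float = 1e-8) -> KRResult:
    """Balance a symmetric non-negative contact matrix.

    Rows with fewer than ``min_nonzero_frac`` nonzero entries are masked
    before balancing; on the unmasked submatrix the returned scaling x > 0
    makes diag(x) A diag(x) have equal row sums (coefficient of variation
    below 1e-6).  Falls back to iterative proportional scaling with a
    warning if the Newton iteration stalls.
    """
    sparse = sp.issparse(matrix)
    A = matrix.tocsr().astype(float) if sparse else np.asarray(matrix, dtype=float)
    n = A.shape[0]
    if A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    diff = abs(A - A.T)
    max_diff = diff.max() if not sparse else (diff.max() if diff.nnz else 0.0)
    scale_ref = A.max() if not sparse else (A.max() if A.nnz else 0.0)
    if (A < 0).sum() if not sparse else (A.data < 0).sum():
        raise ValueError("matrix must be non-negative")
    if max_diff > symmetry_rtol * max(scale_ref, 1.0):
        raise ValueError("matrix is not symmetric within tolerance")

    nnz_row = (A != 0).sum(axis=1)
    nnz_row = np.asarray(nnz_row).ravel()
    mask = nnz_row < max(min_nonzero_frac * n, 1)
    scale = np.full(n, np.nan)
    keep = ~mask
    if keep.sum() == 0:
        return KRResult(scale, mask, False, "none")
    sub = A[np.ix_(keep, keep)] if not sparse else A[keep][:, keep]
    # precondition: scale by row sums so the iteration starts near balance
    rs = np.asarray(sub.sum(axis=1)).ravel()
    if (rs == 0).any():
        mask[np.flatnonzero(keep)[rs == 0]] = True
        keep = ~mask
        if keep.sum() == 0:
            return KRResult(scale, mask, False, "none")
        sub = A[np.ix_(keep, keep)] if not sparse else A[keep][:, keep]
        rs = np.asarray(sub.sum(axis=1)).ravel()
    d0 = 1.0 / np.sqrt(rs)
    pre = (sp.diags(d0) @ sub @ sp.diags(d0)) if sparse else sub * np.outer(d0, d0)
    x, ok = _bnewt(pre, tol=tol)
    method = "KR"
    if not ok or not np.isfinite(x).all() or (x <= 0).any():
        warnings.warn("KR iteration stalled; falling back to iterative "
                      "proportional scaling")
        x, ok = _sinkhorn(pre)
        method = "sinkhorn"
    scale[keep] = x * d0
    return KRResult(scale, mask, ok, method)


# ---------------------------------------------------------------------------
# contact extraction
# ---------------------------------------------------------------------------

@dataclass
class ContactTable:
    """rDNA-anchored contacts accumulated per genomic bin."""

    bins: pd.DataFrame  # Chromosome, Start, End, RawCount, Score
    bin_size: int
    genome: Genome
    replicate: str = ""
    n_retained: int = 0
    n_both_outside: int = 0
    n_both_inside: int = 0
    n_malformed: int = 0

    def __post_init__(self) -> None:
        df = self.bins
        if len(df) and ((df["Start"] % self.bin_size != 0).any()):
            raise ValueError("bins not aligned to the bin-size grid")
        if len(df) and ((df["RawCount"] < 0).any()):
            raise ValueError("negative counts")

    @property
    def n_unique(self) -> int:
        return len(self.bins)

    def write(self, path: str | os.PathLike) -> None:
        self.bins.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | os.PathLike, bin_size: int, genome: Genome,
             replicate: str = "") -> "ContactTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"Chromosome": str}),
                   bin_size, genome, replicate)


def read_pairs(path: str | os.PathLike) -> tuple[pd.DataFrame, int]:
    """Parse 7-column pairs text (readID chr1 pos1 chr2 pos2 strand1
    strand2); returns (pairs, n_malformed)."""
    rows = []
    malformed = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                malformed += 1
                continue
            try:
                rows.append((parts[1], int(parts[2]), parts[3], int(parts[4])))
            except ValueError:
                malformed += 1
    if malformed:
        warnings.warn(f"{malformed} malformed pair lines skipped")
    return (pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"]),
            malformed)


def extract_rdna_contacts(pairs: pd.DataFrame | str | os.PathLike,
                          index: GenomeIndex, bin_size: int = 5_000,
                          balancing: dict[str, np.ndarray] | None = None,
                          replicate: str = "") -> ContactTable:
    """Retain pairs with exactly one end in the rDNA unit and bin the other
    end.

    Pairs with both ends inside the unit are tallied separately (the
    analysis targets contacts between rRNA genes and the rest of the
    genome).  When ``balancing`` maps chromosome -> per-bin weights, the
    score is raw count x weight; otherwise score = raw count.
    """
    malformed = 0
    if not isinstance(pairs, pd.DataFrame):
        pairs, malformed = read_pairs(pairs)
    c1 = pairs["chrom1"].to_numpy(dtype=object)
    c2 = pairs["chrom2"].to_numpy(dtype=object)
    p1 = pairs["pos1"].to_numpy(dtype=np.int64)
    p2 = pairs["pos2"].to_numpy(dtype=np.int64)
    in1 = index.in_rdna(c1, p1)
    in2 = index.in_rdna(c2, p2)
    both_in = in1 & in2
    both_out = ~in1 & ~in2
    keep = in1 ^ in2
    other_chrom = np.where(in1[keep], c2[keep], c1[keep])
    other_pos = np.where(in1[keep], p2[keep], p1[keep])
    starts = (other_pos // bin_size) * bin_size
    df = (pd.DataFrame({"Chromosome": other_chrom, "Start": starts})
          .groupby(["Chromosome", "Start"], observed=True)
          .size().reset_index(name="RawCount"))
    df["Chromosome"] = df["Chromosome"].astype(str)
    sizes = index.genome.sizes
    df["End"] = np.minimum(df["Start"] + bin_size,
                           df["Chromosome"].map(sizes).to_numpy())
    if balancing is not None:
        w = np.full(len(df), np.nan)
        for chrom, weights in balancing.items():
            sel = (df["Chromosome"] == chrom).to_numpy()
            idx = (df.loc[sel, "Start"].to_numpy() // bin_size).astype(int)
            w[sel] = np.asarray(weights)[idx]
        df["Score"] = df["RawCount"] * w
    else:
        df["Score"] = df["RawCount"].astype(float)
    df = df[["Chromosome", "Start", "End", "RawCount", "Score"]] \
        .sort_values(["Chromosome", "Start"]).reset_index(drop=True)
    return ContactTable(df, bin_size, index.genome, replicate,
                        n_retained=int(keep.sum()),
                        n_both_outside=int(both_out.sum()),
                        n_both_inside=int(both_in.sum()),
                        n_malformed=malformed)


def read_juicer_dump(path: str | os.PathLike, anchor_chrom: str,
                     other_chrom: str, index: GenomeIndex,
                     bin_size: int = 5_000, replicate: str = "") -> ContactTable:
    """Build a ContactTable from Juicer-dump-style text (pos1 pos2 count)
    for one chromosome pair, where pos1 lies on the rDNA-bearing chromosome.

    Rows whose pos1 bin overlaps the rDNA unit and whose pos2 bin does not
    are retained.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["pos1", "pos2", "count"])
    rchrom, rstart, rend = index.rdna_interval
    if anchor_chrom != rchrom:
        raise ValueError("anchor chromosome does not carry the rDNA unit")
    in1 = (df["pos1"] + bin_size > rstart) & (df["pos1"] < rend)
    in2 = np.zeros(len(df), dtype=bool)
    if other_chrom == rchrom:
        in2 = ((df["pos2"] + bin_size > rstart) & (df["pos2"] < rend)).to_numpy()
    keep = in1.to_numpy() & ~in2
    sub = df[keep]
    out = (sub.groupby("pos2")["count"].sum().reset_index()
           .rename(columns={"pos2": "Start", "count": "RawCount"}))
    out.insert(0, "Chromosome", other_chrom)
    out["End"] = np.minimum(out["Start"] + bin_size,
                            index.genome.sizes[other_chrom])
    out["Score"] = out["RawCount"].astype(float)
    out = out[["Chromosome", "Start", "End", "RawCount", "Score"]]
    return ContactTable(out.reset_index(drop=True), bin_size, index.genome,
                        replicate, n_retained=int(sub["count"].sum()))


def filter_blacklist(table: ContactTable, blacklist: DomainSet,
                     ) -> tuple[ContactTable, int]:
    """Drop bins overlapping any blacklist interval by >= 1 bp; returns
    (filtered table, number of bins removed)."""
    if table.bins.empty or blacklist.is_empty:
        return table, 0
    df = table.bins
    bad = np.zeros(len(df), dtype=bool)
    for chrom, sub in blacklist.merge().df.groupby("Chromosome", observed=True):
        sel = (df["Chromosome"] == str(chrom)).to_numpy()
        if not sel.any():
            continue
        s = df.loc[sel, "Start"].to_numpy()
        e = df.loc[sel, "End"].to_numpy()
        bs = sub["Start"].to_numpy()
        be = sub["End"].to_numpy()
        # merged intervals sorted by start: the last interval starting before
        # the bin end has the largest end among candidates, so one probe
        # decides overlap
        i = np.searchsorted(bs, e, side="left") - 1
        hit = (i >= 0) & (be[np.clip(i, 0, None)] > s)
        bad[np.flatnonzero(sel)] = hit
    removed = int(bad.sum())
    out = ContactTable(df[~bad].reset_index(drop=True), table.bin_size,
                       table.genome, table.replicate,
                       table.n_retained, table.n_both_outside,
                       table.n_both_inside, table.n_malformed)
    return out, removed


def common_contacts(tables: list[ContactTable], min_count: int = 1,
                    ) -> tuple[ContactTable, pd.DataFrame]:
    """Bins present (raw count >= min_count) in every replicate.

    Score of a common bin is the mean of the replicate scores.  Also returns
    the per-replicate presence matrix over the union of bins.
    """
    if len(tables) < 2:
        raise ValueError("need at least two replicates")
    bs = tables[0].bin_size
    genome = tables[0].genome
    for t in tables[1:]:
        if t.bin_size != bs or t.genome != genome:
            raise ValueError("inconsistent binning between replicates")
    keys = ["Chromosome", "Start", "End"]
    presence = None
    for i, t in enumerate(tables):
        sub = t.bins[keys].copy()
        sub[f"rep{i}"] = (t.bins["RawCount"] >= min_count).to_numpy()
        presence = sub if presence is None else presence.merge(
            sub, on=keys, how="outer")
    rep_cols = [c for c in presence.columns if c.startswith("rep")]
    presence[rep_cols] = presence[rep_cols].isin([True])
    common_keys = presence[presence[rep_cols].all(axis=1)][keys]
    merged = common_keys.copy()
    score_cols = []
    for i, t in enumerate(tables):
        merged = merged.merge(
            t.bins[keys + ["Score", "RawCount"]].rename(
                columns={"Score": f"s{i}", "RawCount": f"c{i}"}),
            on=keys, how="left")
        score_cols.append(f"s{i}")
    merged["Score"] = merged[score_cols].mean(axis=1)
    merged["RawCount"] = merged[[f"c{i}" for i in range(len(tables))]].sum(axis=1)
    out = merged[keys + ["RawCount", "Score"]] \
        .sort_values(["Chromosome", "Start"]).reset_index(drop=True)
    return (ContactTable(out, bs, genome, replicate="common"), presence)


def quintile_distribution(table: ContactTable, index: GenomeIndex,
                          ) -> tuple[pd.DataFrame, np.ndarray]:
    """Proportion of unique contact bins in 5 equal-length chromosome
    segments (segment 1 = the assembly-start, centromere-proximal end).

    Returns (per-chromosome proportions, mean across chromosomes)."""
    if table.bins.empty:
        raise ValueError("empty contact table")
    rows = {}
    for chrom, sub in table.bins.groupby("Chromosome", observed=True):
        chrom = str(chrom)
        size = table.genome.sizes[chrom]
        if size < 5 * table.bin_size:
            warnings.warn(f"{chrom} shorter than 5 bins; excluded")
            continue
        mid = (sub["Start"] + sub["End"]) // 2
        q = np.minimum((mid * 5 // size).astype(int), 4)
        counts = np.bincount(q, minlength=5).astype(float)
        rows[chrom] = counts / counts.sum()
    per_chrom = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"Q{i + 1}" for i in range(5)])
    return per_chrom, per_chrom.mean(axis=0).to_numpy()


def per_chromosome_summary(table: ContactTable) -> pd.DataFrame:
    """Unique-contact counts and score distribution per chromosome."""
    if table.bins.empty:
        raise ValueError("empty contact table")
    g = table.bins.groupby("Chromosome", observed=True)
    out = g.agg(n_unique=("Start", "size"),
                mean_score=("Score", "mean"),
                median_score=("Score", "median"),
                total_raw=("RawCount", "sum")).reset_index()
    return out.sort_values("n_unique", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# cis matrices from pairs (for balancing and compartments)
# ---------------------------------------------------------------------------

def bin_pairs_cis_matrix(pairs: pd.DataFrame, genome: Genome, chrom: str,
                         bin_size: int) -> sp.csr_matrix:
    """Symmetric binned cis contact matrix for one chromosome."""
    sub = pairs[(pairs["chrom1"] == chrom) & (pairs["chrom2"] == chrom)]
    n = -(-genome.sizes[chrom] // bin_size)
    i = (sub["pos1"].to_numpy() // bin_size).astype(np.int64)
    j = (sub["pos2"].to_numpy() // bin_size).astype(np.int64)
    m = sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()
    return m + m.T


def cis_balancing_weights(pairs: pd.DataFrame, index: GenomeIndex,
                          bin_size: int) -> dict[str, np.ndarray]:
    """Per-chromosome KR weights from the full cis matrices.

    Weights are rescaled to mean 1 over unmasked bins; masked bins get NaN.
    """
    weights: dict[str, np.ndarray] = {}
    for chrom in index.genome.names:
        m = bin_pairs_cis_matrix(pairs, index.genome, chrom, bin_size)
        res = kr_balance(m)
        x = res.scale
        finite = np.isfinite(x)
        if finite.any():
            x = x / np.nanmean(x)
        weights[chrom] = x
    return weights
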