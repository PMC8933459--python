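"""A/B compartment eigenvectors and between-state switch classification.

Compartments are computed per chromosome at 100-kb bins in the standard
way: the cis contact matrix is KR-balanced, distance-normalized
(observed/expected), converted to a Pearson correlation matrix, and
eigendecomposed.  Among the top eigenvectors the compartment eigenvector is
the one most correlated with a reference track such as gene density (sparse
maps can push a coverage-driven component ahead of it), and its sign is
oriented so that positive values (A, the active compartment) correlate
positively with the reference.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import Genome
from .intervals import DomainSet
from .tracks import BinnedTrack

CATEGORIES = ("A to A", "B to B", "B to A", "A to B",
              "B to b", "b to B", "a to A", "A to a")


def _oe_correlation(A: np.ndarray) -> np.ndarray:
    """Observed/expected by distance-stratified means, then column Pearson
    correlation."""
    n = A.shape[0]
    oe = np.zeros_like(A)
    for d in range(n):
        diag = np.diagonal(A, offset=d)
        m = diag.mean()
        if m > 0:
            vals = diag / m
            idx = np.arange(n - d)
            oe[idx, idx + d] = vals
            oe[idx + d, idx] = vals
    # columns with (near-)zero variance carry no compartment information:
    # a perfectly uniform O/E map must abstain rather than return noise
    col_var = oe.var(axis=0)
    scale = max(float(np.mean(oe) ** 2), 1e-300)
    degenerate = col_var / scale < 1e-14
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(oe)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    return corr


def compartment_eigenvector(matrices: dict[str, np.ndarray | sp.spmatrix],
                            genome: Genome, bin_size: int,
                            reference: BinnedTrack,
                            min_nonzero_frac: float = 0.10,
                            balance: bool = True,
                            n_candidates: int = 3) -> BinnedTrack:
    """Compartment eigenvector of the balanced O/E correlation per
    chromosome, sign-oriented against ``reference`` (positive = A).

    Of the ``n_candidates`` top eigenvectors, the one with the highest
    absolute correlation with the reference track is taken.  Bins whose
    matrix row has fewer than ``min_nonzero_frac`` nonzero entries, or
    whose O/E column is degenerate, are masked.
    """
    if reference.genome != genome or reference.bin_size != bin_size:
        raise ValueError("reference track must share the compartment binning")
    values: dict[str, np.ndarray] = {}
    mask: dict[str, np.ndarray] = {}
    for chrom in genome.names:
        n = -(-genome.sizes[chrom] // bin_size)
        ev = np.zeros(n)
        msk = np.ones(n, dtype=bool)
        values[chrom], mask[chrom] = ev, msk
        M = matrices.get(chrom)
        if M is None:
            warnings.warn(f"no matrix for {chrom}; all bins masked")
            continue
        A = np.asarray(M.todense() if sp.issparse(M) else M, dtype=float)
        if A.shape != (n, n):
            raise ValueError(f"matrix shape mismatch on {chrom}")
        if balance:
            from .hic import kr_balance
            res = kr_balance(A, min_nonzero_frac=min_nonzero_frac)
            keep = ~res.mask
            if keep.sum() < 3:
                warnings.warn(f"{chrom}: too few covered bins; masked")
                continue
            sub_mat = res.balanced(A)
        else:
            nnz = (A != 0).sum(axis=1)
            keep = nnz >= max(min_nonzero_frac * n, 1)
            if keep.sum() < 3:
                warnings.warn(f"{chrom}: too few covered bins; masked")
                continue
            sub_mat = A[np.ix_(keep, keep)]
        corr = _oe_correlation(sub_mat)
        good = np.isfinite(corr).all(axis=1)
        if good.sum() < 3:
            warnings.warn(f"{chrom}: degenerate O/E (no structure); masked")
            continue
        sub = corr[np.ix_(good, good)]
        w, v = np.linalg.eigh(sub)
        idx = np.flatnonzero(keep)[good]
        ref = reference.values[chrom][idx]
        usable = ~reference.mask[chrom][idx]
        lead = v[:, -1]
        if usable.sum() >= 2 and np.std(ref[usable]) > 0:
            best_r = None
            for k in range(1, min(n_candidates, v.shape[1]) + 1):
                cand = v[:, -k]
                if np.std(cand[usable]) == 0:
                    continue
                r = np.corrcoef(cand[usable], ref[usable])[0, 1]
                if np.isfinite(r) and (best_r is None or abs(r) > abs(best_r)):
                    best_r, lead = r, cand
            if best_r is not None and best_r < 0:
                lead = -lead
        ev[idx] = lead
        msk[idx] = False
    return BinnedTrack(genome, bin_size, values, mask)


@dataclass
class SwitchCall:
    """Per-bin compartment switch categories between two states."""

    genome: Genome
    bin_size: int
    categories: dict[str, np.ndarray]  # object arrays; "NA" where masked
    delta: dict[str, np.ndarray]       # ev2 - ev1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.genome.names:
            n = len(self.categories[chrom])
            starts = np.arange(n, dtype=np.int64) * self.bin_size
            rows.append(pd.DataFrame({
                "Chromosome": chrom, "Start": starts,
                "End": np.minimum(starts + self.bin_size,
                                  self.genome.sizes[chrom]),
                "Category": self.categories[chrom],
                "Delta": self.delta[chrom]}))
        return pd.concat(rows, ignore_index=True)

    def write_bed(self, path) -> None:
        df = self.to_frame()
        df[df["Category"] != "NA"].to_csv(path, sep="\t", header=False,
                                          index=False)


def classify_switch(ev1: BinnedTrack, ev2: BinnedTrack,
                    delta_min: float = 0.0,
                    case_convention: str = "magnitude") -> SwitchCall:
    """Classify per-bin eigenvector changes between two cell states.

    Sign changes are full switches (B to A / A to B).  Same-sign changes of
    at least ``delta_min`` get a lowercase letter; under the default
    "magnitude" convention the lowercase letter marks the weaker state
    (|ev| closer to 0), e.g. (-1.0, -0.2) is "B to b".  Under the "delta"
    convention the lowercase letter is placed on the smaller eigenvector
    value instead, so within B a decrease is "B to b" and an increase is
    "b to B".  Changes below delta_min, and bins at exactly 0, are stable.
    """
    if not ev1.same_binning(ev2):
        raise ValueError("eigenvector tracks are not on the same bins")
    if case_convention not in ("magnitude", "delta"):
        raise ValueError("case_convention must be 'magnitude' or 'delta'")
    categories: dict[str, np.ndarray] = {}
    deltas: dict[str, np.ndarray] = {}
    for chrom in ev1.genome.names:
        a = ev1.values[chrom]
        b = ev2.values[chrom]
        masked = ev1.mask[chrom] | ev2.mask[chrom]
        cat = np.full(len(a), "NA", dtype=object)
        d = b - a
        pos1, pos2 = a > 0, b > 0
        neg1, neg2 = a < 0, b < 0
        stable = np.abs(d) < max(delta_min, 1e-300)
        cat[~masked & pos1 & neg2] = "A to B"
        cat[~masked & neg1 & pos2] = "B to A"
        same_a = ~masked & pos1 & pos2
        same_b = ~masked & neg1 & neg2
        cat[same_a & stable] = "A to A"
        cat[same_b & stable] = "B to B"
        moved_a = same_a & ~stable
        moved_b = same_b & ~stable
        if case_convention == "magnitude":
            cat[moved_b & (np.abs(b) < np.abs(a))] = "B to b"
            cat[moved_b & (np.abs(b) >= np.abs(a))] = "b to B"
            cat[moved_a & (np.abs(b) >= np.abs(a))] = "a to A"
            cat[moved_a & (np.abs(b) < np.abs(a))] = "A to a"
        else:
            cat[moved_b & (d < 0)] = "B to b"
            cat[moved_b & (d > 0)] = "b to B"
            cat[moved_a & (d > 0)] = "a to A"
            cat[moved_a & (d < 0)] = "A to a"
        # zero-valued bins with no sign are left stable in their partner's state
        zero = ~masked & (a == 0) & (cat == "NA")
        cat[zero & (b > 0)] = "A to A"
        cat[zero & (b < 0)] = "B to B"
        cat[~masked & (b == 0) & (cat == "NA") & (a > 0)] = "A to A"
        cat[~masked & (b == 0) & (cat == "NA") & (a < 0)] = "B to B"
        cat[~masked & (a == 0) & (b == 0)] = "NA"
        categories[chrom] = cat
        deltas[chrom] = d
    return SwitchCall(ev1.genome, ev1.bin_size, categories, deltas)


def _bin_category_arrays(calls: "SwitchCall | BinnedTrack",
                         ) -> tuple[Genome, int, dict[str, np.ndarray]]:
    if isinstance(calls, SwitchCall):
        return calls.genome, calls.bin_size, calls.categories
    cats = {}
    for chrom in calls.genome.names:
        v = calls.values[chrom]
        c = np.full(len(v), "NA", dtype=object)
        c[~calls.mask[chrom] & (v > 0)] = "A"
        c[~calls.mask[chrom] & (v < 0)] = "B"
        cats[chrom] = c
    return calls.genome, calls.bin_size, cats


def fraction_by_category(domains: DomainSet,
                         calls: "SwitchCall | BinnedTrack") -> dict[str, float]:
    """bp fraction of a domain set overlapping bins of each category.

    Fractions over the exhaustive category set (including "NA") sum to 1.
    """
    genome, bin_size, cats = _bin_category_arrays(calls)
    if domains.genome != genome:
        raise ValueError("mismatched genome contexts")
    bp: dict[str, float] = {}
    total = 0
    for iv in domains.merge().df.itertuples(index=False):
        chrom = iv.Chromosome
        c = cats[chrom]
        b0 = iv.Start // bin_size
        b1 = (iv.End - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo = max(iv.Start, b * bin_size)
            hi = min(iv.End, (b + 1) * bin_size)
            bp[c[b]] = bp.get(c[b], 0) + (hi - lo)
            total += hi - lo
    if total == 0:
        return {}
    return {k: v / total for k, v in sorted(bp.items())}
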