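"""Contact matrices: binning, ICE balancing, resolution analysis, summaries.

The whole genome lives in one dense symmetric matrix indexed by global bin id
(see :class:`~hiclite.genome.GenomeBins`); per-chromosome cis blocks and
inter-chromosomal trans blocks are views into it.  Dense storage is deliberate:
every problem size this package targets is a few thousand bins at most, and
dense arrays make the window/convolution operations downstream both simple and
fast.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import GenomeBins
from .pairs import ValidPairs

__all__ = [
    "ContactMatrix", "ResolutionReport", "bin_contacts", "ice_normalize",
    "bin_coverage", "map_resolution", "cis_trans_summary", "delta_matrix",
    "write_triplets", "read_triplets",
]

#: candidate bin sizes for resolution analysis (bp), coarse to fine
RESOLUTION_GRID = (1_000_000, 500_000, 200_000, 100_000,
                   40_000, 20_000, 10_000, 5_000, 1_000)


@dataclass
class ContactMatrix:
    """A binned, symmetric genome-wide contact matrix.

    Attributes
    ----------
    bins : GenomeBins
    counts : ndarray (n, n)
        Symmetric contact values (raw counts, balanced values, or O/E —
        see ``state``).
    bias : ndarray (n,)
        ICE bias (accumulated divisor) per bin; 1.0 before balancing, NaN for
        masked bins.
    mask : ndarray (n,) of bool
        True where the bin is filtered out (low coverage).
    state : str
        "raw", "balanced" or "oe".
    total_pairs : int
        Number of contact records binned in.
    """

    bins: GenomeBins
    counts: np.ndarray
    bias: np.ndarray = None
    mask: np.ndarray = None
    state: str = "raw"
    total_pairs: int = 0

    def __post_init__(self):
        n = self.bins.n_bins_total
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match genome bins")
        if self.bias is None:
            self.bias = np.ones(n)
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)

    # -- views -------------------------------------------------------------
    def cis(self, chrom: str) -> np.ndarray:
        s = self.bins.chrom_slice(chrom)
        return self.counts[s, s]

    def trans(self, chrom1: str, chrom2: str) -> np.ndarray:
        return self.counts[self.bins.chrom_slice(chrom1),
                           self.bins.chrom_slice(chrom2)]

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.mask[self.bins.chrom_slice(chrom)]

    @property
    def total(self) -> float:
        """Sum over the upper triangle including the diagonal.

        Equals the number of binned records for a raw matrix.
        """
        return float(np.triu(self.counts).sum())

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.bins, self.counts.copy(), self.bias.copy(),
                             self.mask.copy(), self.state, self.total_pairs)

    def scaled_to(self, target_total: float) -> "ContactMatrix":
        """Depth-scale so the (upper-triangle) total equals ``target_total``."""
        out = self.copy()
        t = self.total
        if t <= 0:
            raise ValueError("cannot scale an all-zero matrix")
        out.counts = out.counts * (target_total / t)
        return out


def bin_contacts(pairs: ValidPairs, genome: GenomeBins) -> ContactMatrix:
    """Bin valid pairs into a symmetric contact matrix.

    Each pair increments the cell (bin(pos1), bin(pos2)); both triangles are
    filled so cis blocks are symmetric.  ``matrix.total`` (upper triangle)
    equals the record count exactly.
    """
    n = genome.n_bins_total
    counts = np.zeros((n, n))
    if len(pairs):
        df = pairs.df
        off1 = df["chrom1"].map(genome._offsets).to_numpy()
        off2 = df["chrom2"].map(genome._offsets).to_numpy()
        b1 = (df["pos1"].to_numpy() - 1) // genome.bin_size + off1
        b2 = (df["pos2"].to_numpy() - 1) // genome.bin_size + off2
        lo = np.minimum(b1, b2).astype(np.int64)
        hi = np.maximum(b1, b2).astype(np.int64)
        flat = np.bincount(lo * n + hi, minlength=n * n).reshape(n, n)
        counts = flat + flat.T - np.diag(np.diag(flat))
        counts = counts.astype(float)
    return ContactMatrix(genome, counts, total_pairs=len(pairs))


def ice_normalize(matrix: ContactMatrix, max_iter: int = 100,
                  low_pct: float = 0.02, high_pct: float = 0.0,
                  eps: float = 0.1) -> ContactMatrix:
    """Iterative correction (ICE) of a raw contact matrix.

    The bottom ``low_pct`` fraction of bins by total coverage (plus any
    zero-coverage bin) is masked; then rows/columns are iteratively divided by
    their relative row sum until the maximum relative deviation of unmasked
    row sums from their mean falls below ``eps``, or ``max_iter`` sweeps.
    Defaults follow the standard HiC-Pro ICED parameterisation
    (MAX_ITER=100, FILTER_LOW_COUNT_PERC=0.02, FILTER_HIGH_COUNT_PERC=0,
    EPS=0.1).
    """
    if matrix.state != "raw":
        raise ValueError("ice_normalize expects an unnormalized matrix")
    W = matrix.counts.astype(float).copy()
    n = W.shape[0]
    cov = W.sum(axis=1)
    if not np.any(cov > 0):
        raise ValueError("nothing to balance: all-zero matrix")

    mask = matrix.mask.copy()
    mask |= cov == 0
    if low_pct > 0:
        thr = np.quantile(cov, low_pct)
        mask |= cov <= thr
    if high_pct > 0:
        thr_hi = np.quantile(cov, 1.0 - high_pct)
        mask |= cov >= thr_hi
    if mask.all():
        raise ValueError("nothing to balance: every bin masked")

    W[mask, :] = 0.0
    W[:, mask] = 0.0
    bias = np.ones(n)
    for _ in range(max_iter):
        s = W.sum(axis=1)
        live = s[~mask]
        rel = np.ones(n)
        rel[~mask] = live / live.mean()
        if np.max(np.abs(rel[~mask] - 1.0)) < eps:
            break
        W /= rel[:, None]
        W /= rel[None, :]
        bias *= rel

    bias_out = bias.copy()
    bias_out[mask] = np.nan
    return ContactMatrix(matrix.bins, W, bias=bias_out, mask=mask,
                         state="balanced", total_pairs=matrix.total_pairs)


# ---------------------------------------------------------------------------
# resolution analysis
# ---------------------------------------------------------------------------

@dataclass
class ResolutionReport:
    """Outcome of the percentile-depth map-resolution procedure.

    For each candidate bin size the per-bin coverage vector is sorted in
    descending order and the depths at the 75th/80th/90th percentile positions
    are read off; a bin size is *achieved* when the depth at the decision
    percentile (default the 80th) is at least ``depth_threshold``.
    """

    candidate_sizes: list[int]
    depth_threshold: int
    percentile: float
    ends_per_pair: int
    per_size: dict[int, dict] = field(default_factory=dict)
    finest_achieved: int | None = None

    def achieved(self, size: int) -> bool:
        return bool(self.per_size[size]["achieved"])

    def to_json(self, path=None) -> str:
        payload = {
            "candidate_sizes": self.candidate_sizes,
            "depth_threshold": self.depth_threshold,
            "percentile": self.percentile,
            "ends_per_pair": self.ends_per_pair,
            "finest_achieved": self.finest_achieved,
            "per_size": {str(k): v for k, v in self.per_size.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def bin_coverage(pairs: ValidPairs, genome: GenomeBins,
                 ends_per_pair: int = 2) -> np.ndarray:
    """Per-bin coverage depth from valid pairs.

    By default each pair contributes both of its ends (read-depth intuition);
    ``ends_per_pair=1`` counts only the first end.
    """
    n = genome.n_bins_total
    if not len(pairs):
        return np.zeros(n, dtype=np.int64)
    df = pairs.df
    off1 = df["chrom1"].map(genome._offsets).to_numpy()
    b1 = (df["pos1"].to_numpy() - 1) // genome.bin_size + off1
    cov = np.bincount(b1.astype(np.int64), minlength=n)
    if ends_per_pair == 2:
        off2 = df["chrom2"].map(genome._offsets).to_numpy()
        b2 = (df["pos2"].to_numpy() - 1) // genome.bin_size + off2
        cov = cov + np.bincount(b2.astype(np.int64), minlength=n)
    return cov


def _percentile_depth(sorted_desc: np.ndarray, percentile: float) -> int:
    """Depth at the 1-based position ceil(percentile * n) of a descending sort."""
    n = len(sorted_desc)
    pos = max(1, math.ceil(percentile * n))
    return int(sorted_desc[pos - 1])


def map_resolution(pairs: ValidPairs, chromsizes: dict[str, int],
                   candidate_sizes=RESOLUTION_GRID, depth_threshold: int = 1000,
                   percentile: float = 0.80,
                   ends_per_pair: int = 2) -> ResolutionReport:
    """Determine map resolution by the percentile-depth procedure.

    For each candidate bin size, bins are sorted in descending order of
    coverage; the size is achieved when the depth at the 80th-percentile
    position reaches ``depth_threshold`` (default 1000).  The finest achieved
    size is the map resolution.  Depths at the 75th and 90th percentile
    positions and the fraction of bins above threshold are reported alongside.
    """
    report = ResolutionReport(candidate_sizes=list(candidate_sizes),
                              depth_threshold=depth_threshold,
                              percentile=percentile,
                              ends_per_pair=ends_per_pair)
    for size in candidate_sizes:
        genome = GenomeBins(chromsizes, size)
        cov = bin_coverage(pairs, genome, ends_per_pair=ends_per_pair)
        if len(pairs) == 0:
            entry = {"n_bins": genome.n_bins_total, "depth_p75": 0,
                     "depth_p80": 0, "depth_p90": 0,
                     "frac_above_threshold": 0.0, "achieved": False}
        else:
            srt = np.sort(cov)[::-1]
            d75 = _percentile_depth(srt, 0.75)
            d80 = _percentile_depth(srt, percentile)
            d90 = _percentile_depth(srt, 0.90)
            entry = {
                "n_bins": genome.n_bins_total,
                "depth_p75": d75, "depth_p80": d80, "depth_p90": d90,
                "frac_above_threshold": float(np.mean(cov > depth_threshold)),
                "achieved": bool(d80 >= depth_threshold),
            }
        report.per_size[size] = entry
    achieved = [s for s in candidate_sizes if report.per_size[s]["achieved"]]
    report.finest_achieved = min(achieved) if achieved else None
    return report


# ---------------------------------------------------------------------------
# summaries and differences
# ---------------------------------------------------------------------------

def cis_trans_summary(matrix: ContactMatrix, flag_factor: float = 3.0):
    """Mean cis interaction per chromosome and mean trans interaction per
    chromosome pair, over unmasked cells.

    A trans block is flagged as a rearrangement candidate when its mean exceeds
    ``flag_factor`` times the median trans-block mean (the signature used to
    spot e.g. a translocation-driven trans hotspot).

    Returns
    -------
    (cis_means, trans_df) where cis_means maps chromosome -> mean and trans_df
    has columns chrom1, chrom2, mean_trans, flagged.
    """
    chroms = matrix.bins.chrom_names
    cis_means = {}
    for c in chroms:
        m = matrix.cis(c)
        keep = ~matrix.chrom_mask(c)
        sub = m[np.ix_(keep, keep)]
        cis_means[c] = float(sub.mean()) if sub.size else float("nan")
    rows = []
    for i, c1 in enumerate(chroms):
        for c2 in chroms[i + 1:]:
            blk = matrix.trans(c1, c2)
            keep1 = ~matrix.chrom_mask(c1)
            keep2 = ~matrix.chrom_mask(c2)
            sub = blk[np.ix_(keep1, keep2)]
            rows.append((c1, c2, float(sub.mean()) if sub.size else float("nan")))
    trans_df = pd.DataFrame(rows, columns=["chrom1", "chrom2", "mean_trans"])
    if len(trans_df):
        med = np.nanmedian(trans_df["mean_trans"])
        trans_df["flagged"] = trans_df["mean_trans"] > flag_factor * med
    else:
        trans_df["flagged"] = pd.Series(dtype=bool)
    return cis_means, trans_df


def delta_matrix(a: ContactMatrix, b: ContactMatrix) -> ContactMatrix:
    """Signed difference A − B after scaling both to a common contact total.

    Cells masked in either input are NaN in the output.
    """
    if not a.bins.same_bins(b.bins):
        raise ValueError("matrices are on different genome bins")
    target = a.total
    av = a.scaled_to(target).counts
    bv = b.scaled_to(target).counts
    delta = av - bv
    mask = a.mask | b.mask
    delta[mask, :] = np.nan
    delta[:, mask] = np.nan
    return ContactMatrix(a.bins, delta, mask=mask, state=a.state,
                         total_pairs=a.total_pairs)


# ---------------------------------------------------------------------------
# triplet text I/O (binID1 <TAB> binID2 <TAB> value, plus a bins table)
# ---------------------------------------------------------------------------

def write_triplets(matrix: ContactMatrix, matrix_path, bins_path=None) -> None:
    """Export the upper triangle as zero-based triplet text, HiC-Pro style."""
    iu = np.triu_indices_from(matrix.counts)
    vals = matrix.counts[iu]
    keep = vals != 0
    with np.errstate(invalid="ignore"):
        keep &= ~np.isnan(vals)
    df = pd.DataFrame({"binID1": iu[0][keep], "binID2": iu[1][keep],
                       "value": vals[keep]})
    df.to_csv(matrix_path, sep="\t", header=False, index=False)
    if bins_path is not None:
        matrix.bins.bin_table().to_csv(bins_path, sep="\t", header=False,
                                       index=False)


def read_triplets(matrix_path, genome: GenomeBins,
                  state: str = "raw") -> ContactMatrix:
    n = genome.n_bins_total
    counts = np.zeros((n, n))
    try:
        df = pd.read_csv(matrix_path, sep="\t", header=None,
                         names=["binID1", "binID2", "value"])
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["binID1", "binID2", "value"])
    i = df["binID1"].to_numpy(dtype=np.int64)
    j = df["binID2"].to_numpy(dtype=np.int64)
    v = df["value"].to_numpy(dtype=float)
    counts[i, j] = v
    counts[j, i] = v
    total = int(round(np.triu(counts).sum())) if state == "raw" else 0
    return ContactMatrix(genome, counts, state=state, total_pairs=total)
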