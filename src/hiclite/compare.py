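"""Reproducibility and differential interaction analysis across samples.

Two families of comparison live here:

* **Stratum-adjusted correlation (SCC)** — hicrep-style reproducibility.
  Both maps are mean-filter smoothed, pixels are stratified by genomic
  distance, and the per-stratum Pearson correlations r_d are combined with
  weights w_d = N_d * sd(x_d) * sd(y_d); the weighted average is the SCC.

* **Differential interactions** — multiHiCcompare-style.  Samples are first
  jointly normalized by cyclic ("fast") loess of the per-sample log-ratio M
  against genomic distance D, then each pixel is tested for a group
  difference with an exact conditional test: counts within each group are
  summed and the split of the pixel total between groups is compared to its
  null distribution (negative-binomial with a distance-stratum dispersion
  estimated by method of moments; binomial in the zero-dispersion limit).
  BH correction runs across tested pixels.  M (log2 fold change) and D are
  retained per pixel for composite MD export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control

from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .matrix import ContactMatrix

__all__ = ["SccResult", "DiffTable", "smooth_mean_filter", "scc",
           "joint_normalize", "exact_test_diff"]


# ---------------------------------------------------------------------------
# SCC
# ---------------------------------------------------------------------------

def smooth_mean_filter(x: np.ndarray, h: int) -> np.ndarray:
    """Mean filter over the Chebyshev-radius-h neighborhood, edges clipped.

    Each output cell is the mean of the existing cells of the (2h+1)^2
    square around it; h=0 is the identity.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    if h == 0:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    k = 2 * h + 1
    num = ndimage.uniform_filter(x, size=k, mode="constant", cval=0.0) * k * k
    den = ndimage.uniform_filter(np.ones_like(x), size=k, mode="constant",
                                 cval=0.0) * k * k
    return num / den


@dataclass
class SccResult:
    """Stratum-adjusted correlation between two contact maps."""

    h: int
    max_distance_bp: float
    per_stratum: pd.DataFrame   # chrom, distance_bp, r, n, weight
    per_chrom: dict[str, float]
    scc: float                  # genome-wide weighted value


def scc(matrix_a: ContactMatrix, matrix_b: ContactMatrix, h: int = 2,
        max_distance_bp: float = 5e6) -> SccResult:
    """Stratum-adjusted correlation coefficient between two maps.

    Both matrices are smoothed with :func:`smooth_mean_filter`; Pearson
    correlations are computed per distance stratum (one bin of separation
    each, up to ``max_distance_bp``) and averaged with weights
    N_d * sd(x) * sd(y).  Zero-variance strata are skipped.
    """
    if not matrix_a.bins.same_bins(matrix_b.bins):
        raise ValueError("matrices are on different bins")
    g = matrix_a.bins
    B = g.bin_size
    d_max = max(1, int(max_distance_bp // B))
    rows = []
    for chrom in g.chrom_names:
        xs = smooth_mean_filter(matrix_a.cis(chrom), h)
        ys = smooth_mean_filter(matrix_b.cis(chrom), h)
        keep = ~(matrix_a.chrom_mask(chrom) | matrix_b.chrom_mask(chrom))
        nb = xs.shape[0]
        for d in range(1, min(d_max, nb - 1) + 1):
            good = keep[:nb - d] & keep[d:]
            x = np.diagonal(xs, d)[good]
            y = np.diagonal(ys, d)[good]
            if len(x) < 2:
                continue
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append((chrom, d * B, r, len(x), len(x) * sx * sy))
    per_stratum = pd.DataFrame(rows, columns=["chrom", "distance_bp", "r",
                                              "n", "weight"])
    if per_stratum.empty:
        raise ValueError("no usable distance strata for SCC")
    per_chrom = {}
    for chrom, grp in per_stratum.groupby("chrom"):
        per_chrom[chrom] = float(np.average(grp["r"], weights=grp["weight"]))
    genome_wide = float(np.average(per_stratum["r"],
                                   weights=per_stratum["weight"]))
    return SccResult(h, max_distance_bp, per_stratum, per_chrom, genome_wide)


# ---------------------------------------------------------------------------
# joint (fast loess) normalization
# ---------------------------------------------------------------------------

def _pixel_table(matrices: list[ContactMatrix]):
    """Upper-triangle cis pixels where any sample is nonzero.

    Returns (chrom, i, j, D_bp, IF matrix of shape (n_pixels, n_samples)).
    """
    g = matrices[0].bins
    chroms, iis, jjs, dds, vals = [], [], [], [], []
    for chrom in g.chrom_names:
        nb = g.n_bins(chrom)
        blocks = [m.cis(chrom) for m in matrices]
        mask = np.zeros(nb, dtype=bool)
        for m in matrices:
            mask |= m.chrom_mask(chrom)
        iu = np.triu_indices(nb)
        keep = ~mask[iu[0]] & ~mask[iu[1]]
        stack = np.stack([b[iu] for b in blocks], axis=1)
        keep &= np.nan_to_num(stack).sum(axis=1) > 0
        iis.append(iu[0][keep])
        jjs.append(iu[1][keep])
        chroms.extend([chrom] * int(keep.sum()))
        dds.append((iu[1][keep] - iu[0][keep]) * g.bin_size)
        vals.append(stack[keep])
    return (np.array(chroms), np.concatenate(iis), np.concatenate(jjs),
            np.concatenate(dds), np.vstack(vals))


def joint_normalize(matrices: list[ContactMatrix], frac: float = 0.3,
                    cycles: int = 3) -> list[ContactMatrix]:
    """Cyclic loess normalization of several samples against each other.

    Per cycle and sample s: M_s = log2(IF_s + 0.5) − mean over samples of
    log2(IF + 0.5); a LOWESS trend of M_s against genomic distance D is
    fitted and subtracted from log2(IF_s + 0.5).  After the cycles each
    matrix is rescaled to the original mean depth.
    """
    if len(matrices) < 2:
        raise ValueError("joint normalization needs at least 2 matrices")
    g = matrices[0].bins
    for m in matrices[1:]:
        if not m.bins.same_bins(g):
            raise ValueError("matrices are on different bins")
    chroms, ii, jj, dd, IF = _pixel_table(matrices)
    IF = np.nan_to_num(IF.astype(float))
    orig_totals = IF.sum(axis=0)
    mean_total = orig_totals.mean()

    logd = np.log1p(dd.astype(float))
    order = np.argsort(logd)
    delta = 0.01 * (logd.max() - logd.min() + 1e-12)
    L = np.log2(IF + 0.5)
    for _ in range(cycles):
        ref = L.mean(axis=1)
        for s in range(L.shape[1]):
            M = L[:, s] - ref
            trend = _lowess(M[order], logd[order], frac=frac, it=0,
                            delta=delta, return_sorted=False)
            back = np.empty_like(trend)
            back[order] = trend
            L[:, s] = L[:, s] - back
    IF_new = np.maximum(np.exp2(L) - 0.5, 0.0)
    IF_new *= mean_total / IF_new.sum(axis=0)

    out = []
    for s, m in enumerate(matrices):
        counts = np.zeros_like(m.counts, dtype=float)
        for chrom in g.chrom_names:
            sl = g.chrom_slice(chrom)
            sel = chroms == chrom
            block = counts[sl, sl]
            block[ii[sel], jj[sel]] = IF_new[sel, s]
            block[jj[sel], ii[sel]] = IF_new[sel, s]
            counts[sl, sl] = block
        out.append(ContactMatrix(g, counts, bias=m.bias.copy(),
                                 mask=m.mask.copy(), state="balanced",
                                 total_pairs=m.total_pairs))
    return out


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

@dataclass
class DiffTable:
    """Per-pixel differential-interaction results.

    ``table`` columns: chrom, bin1, bin2, D (bp), per-sample IF columns,
    mean1, mean2, M (log2 group-2/group-1), p, q.
    """

    table: pd.DataFrame
    n_tested: int

    def md_composite(self) -> pd.DataFrame:
        """Composite MD data: distance, log fold change, significance flag."""
        df = self.table
        return pd.DataFrame({"D": df["D"], "M": df["M"],
                             "significant": df["q"] < 0.05})

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _exact_p(y1: int, t: int, n1: int, n2: int, phi: float) -> float:
    """Exact conditional two-group test of a pixel total split.

    Under the null both groups share one mean; the group-1 sum y1 of the
    pixel total t follows the conditional law of a sum of n1 NB(mu, phi)
    given the total of n1+n2 such draws.  The p-value sums the probabilities
    of all splits as or less likely than the observed one.  phi -> 0 reduces
    to Binomial(t, n1/(n1+n2)).
    """
    if t == 0:
        return 1.0
    y = np.arange(t + 1)
    if phi < 1e-8:
        logp = (gammaln(t + 1) - gammaln(y + 1) - gammaln(t - y + 1)
                + y * np.log(n1 / (n1 + n2)) + (t - y) * np.log(n2 / (n1 + n2)))
    else:
        r = 1.0 / phi
        a, b = n1 * r, n2 * r
        logp = (gammaln(y + a) - gammaln(y + 1) - gammaln(a)
                + gammaln(t - y + b) - gammaln(t - y + 1) - gammaln(b))
        logp = logp - logsumexp(logp)
    p_obs = logp[y1]
    return float(np.exp(logsumexp(logp[logp <= p_obs + 1e-10])
                        - logsumexp(logp)))


def _stratum_dispersion(IF: np.ndarray, groups: np.ndarray,
                        strata: np.ndarray) -> dict[int, float]:
    """Method-of-moments NB dispersion per distance stratum.

    Pools within-group sample variances (to keep true group effects out of
    the estimate) and solves var = mu + phi * mu^2 by median over pixels.
    """
    out = {}
    for s in np.unique(strata):
        sel = strata == s
        sub = IF[sel]
        means = sub.mean(axis=1)
        wvar = np.zeros(len(sub))
        dof = 0
        for gval in np.unique(groups):
            cols = sub[:, groups == gval]
            if cols.shape[1] > 1:
                wvar += cols.var(axis=1, ddof=1) * (cols.shape[1] - 1)
                dof += cols.shape[1] - 1
        if dof == 0:
            out[int(s)] = 0.0
            continue
        wvar /= dof
        ok = means > 0
        if not ok.any():
            out[int(s)] = 0.0
            continue
        phi = (wvar[ok] - means[ok]) / means[ok] ** 2
        out[int(s)] = float(max(0.0, np.median(phi)))
    return out


def exact_test_diff(group1: list[ContactMatrix], group2: list[ContactMatrix],
                    stratum_bp: float = 1e6,
                    max_total: int = 100_000) -> DiffTable:
    """Exact-test differential interaction analysis between two groups.

    Inputs should be jointly normalized (:func:`joint_normalize`).  Pixels
    where every sample is zero are excluded.  Counts are the rounded
    normalized interaction frequencies; dispersion is estimated per distance
    stratum across samples; p-values are BH-adjusted across tested pixels.
    Pixels with totals above ``max_total`` use a binomial normal-deviate
    approximation for speed.
    """
    if not group1 or not group2:
        raise ValueError("both groups need at least one sample")
    mats = list(group1) + list(group2)
    groups = np.array([0] * len(group1) + [1] * len(group2))
    chroms, ii, jj, dd, IF = _pixel_table(mats)
    IF = np.nan_to_num(IF.astype(float))
    counts = np.round(IF).astype(np.int64)
    strata = (dd // int(stratum_bp)).astype(int)
    disp = _stratum_dispersion(IF, groups, strata)

    n1, n2 = len(group1), len(group2)
    y1 = counts[:, groups == 0].sum(axis=1)
    y2 = counts[:, groups == 1].sum(axis=1)
    tot = y1 + y2
    pvals = np.ones(len(tot))
    from scipy.stats import norm
    for k in range(len(tot)):
        t = int(tot[k])
        if t == 0:
            continue
        phi = disp[int(strata[k])]
        if t > max_total:
            mu = t * n1 / (n1 + n2)
            var = t * (n1 / (n1 + n2)) * (n2 / (n1 + n2)) * (1 + phi * t / (n1 + n2))
            z = (y1[k] - mu) / np.sqrt(var)
            pvals[k] = 2 * norm.sf(abs(z))
        else:
            pvals[k] = _exact_p(int(y1[k]), t, n1, n2, phi)
    pvals = np.clip(pvals, 0.0, 1.0)
    q = false_discovery_control(pvals, method="bh")

    mean1 = IF[:, groups == 0].mean(axis=1)
    mean2 = IF[:, groups == 1].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where((mean1 > 0) & (mean2 > 0),
                     np.log2(mean2 / mean1), np.nan)
    table = pd.DataFrame({"chrom": chroms, "bin1": ii, "bin2": jj, "D": dd})
    for s, m in enumerate(mats):
        table[f"IF_{s}"] = IF[:, s]
    table["mean1"] = mean1
    table["mean2"] = mean2
    table["M"] = M
    table["p"] = pvals
    table["q"] = q
    return DiffTable(table, n_tested=len(table))
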