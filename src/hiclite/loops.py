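"""Chromatin loop detection and aggregate peak analysis (APA).

Loop calling follows the local-neighborhood enrichment idea of HiCCUPS,
simplified to a single resolution: each candidate pixel of the balanced cis
matrix is compared to four local expected values (donut, lower-left,
horizontal and vertical neighborhoods), each mapped back to count scale
through the ICE biases and tested against a Poisson upper tail; BH correction
runs across tested pixels.  A pixel is a loop when it is significant against
the donut and lower-left neighborhoods and enriched at least ``fold_min``
against all four; adjacent significant pixels merge into one call at the
strongest pixel.

APA averages O/E submatrices around a set of anchor pixels; the score is the
center value over the mean of the lower-left corner (short-distance
background).  Sample-minus-reference differencing of APA aggregates supports
cohort-wide loop-strength comparison against a chosen reference sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import false_discovery_control, poisson

from .decay import DecayCurve
from .matrix import ContactMatrix

__all__ = ["LoopSet", "ApaResult", "call_loops", "apa", "apa_vs_reference"]

_NEIGHBORHOODS = ("donut", "lower_left", "horizontal", "vertical")


@dataclass
class LoopSet:
    """Called loop pixels with per-neighborhood enrichment statistics."""

    bins_size: int
    loops: pd.DataFrame  # chrom, bin1, bin2, obs, fold_*, p_*, q_donut, q_lower_left

    def __len__(self) -> int:
        return len(self.loops)

    def anchors(self) -> list[tuple[str, int, int]]:
        return [(r["chrom"], int(r["bin1"]), int(r["bin2"]))
                for _, r in self.loops.iterrows()]

    def to_bedpe(self, path, chromsizes=None) -> None:
        B = self.bins_size
        with open(path, "w") as fh:
            fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tobs\tq\n")
            for _, r in self.loops.iterrows():
                fh.write(f"{r['chrom']}\t{int(r['bin1']) * B}\t"
                         f"{(int(r['bin1']) + 1) * B}\t{r['chrom']}\t"
                         f"{int(r['bin2']) * B}\t{(int(r['bin2']) + 1) * B}\t"
                         f"{r['obs']:.1f}\t{r['q_donut']:.3g}\n")


def _kernels(R: int, r: int):
    """Boolean footprints of the four HiCCUPS-style neighborhoods,
    on a (2R+1)^2 stencil centered at the pixel."""
    size = 2 * R + 1
    di = np.arange(-R, R + 1)[:, None] * np.ones((1, size), dtype=int)
    dj = np.arange(-R, R + 1)[None, :] * np.ones((size, 1), dtype=int)
    cheb = np.maximum(np.abs(di), np.abs(dj))
    inner = cheb <= r
    donut = (cheb <= R) & ~inner & (di != 0) & (dj != 0)
    lower_left = (di >= 1) & (di <= R) & (dj <= -1) & (dj >= -R) & ~inner
    horizontal = (np.abs(di) <= 1) & (np.abs(dj) > r) & (np.abs(dj) <= R)
    vertical = (np.abs(dj) <= 1) & (np.abs(di) > r) & (np.abs(di) <= R)
    return {"donut": donut, "lower_left": lower_left,
            "horizontal": horizontal, "vertical": vertical}


def call_loops(matrix: ContactMatrix, curve: DecayCurve, d_min: int = 2,
               d_max_bp: float = 2e6, donut_R: int = 5, inner_r: int = 2,
               fold_min: float = 1.5, q_max: float = 0.1) -> LoopSet:
    """Call loops on an ICE-balanced matrix with a fitted expected curve.

    ``d_min`` (bins) and ``d_max_bp`` bound the candidate diagonal band.
    """
    if matrix.state != "balanced":
        raise ValueError("call_loops requires an ICE-balanced matrix; "
                         "run ice_normalize first")
    g = matrix.bins
    B = g.bin_size
    d_max = int(d_max_bp // B)
    kernels = _kernels(donut_R, inner_r)

    records = []
    for chrom in g.chrom_names:
        nb = g.n_bins(chrom)
        off = g.offset(chrom)
        bal = matrix.cis(chrom).astype(float).copy()
        m = matrix.chrom_mask(chrom)
        bias = matrix.bias[g.chrom_slice(chrom)]
        bal[m, :] = 0.0
        bal[:, m] = 0.0

        idx = np.arange(nb)
        dist = np.abs(idx[:, None] - idx[None, :]) * B
        E = curve.expected_at(dist.ravel()).reshape(nb, nb)
        E = np.where(np.isfinite(E), E, 0.0)
        E[m, :] = 0.0
        E[:, m] = 0.0

        conv_o = {k: ndimage.convolve(bal, kern.astype(float),
                                      mode="constant", cval=0.0)
                  for k, kern in kernels.items()}
        conv_e = {k: ndimage.convolve(E, kern.astype(float),
                                      mode="constant", cval=0.0)
                  for k, kern in kernels.items()}

        ii, jj = np.nonzero(np.triu(np.ones((nb, nb), dtype=bool), k=d_min)
                            & ~np.triu(np.ones((nb, nb), dtype=bool),
                                       k=d_max + 1))
        good = ~m[ii] & ~m[jj] & (E[ii, jj] > 0)
        ii, jj = ii[good], jj[good]
        if len(ii) == 0:
            continue

        raw_obs = bal[ii, jj] * bias[ii] * bias[jj]
        row = {"chrom": chrom, "bin1": ii, "bin2": jj, "obs": raw_obs}
        for k in _NEIGHBORHOODS:
            num = conv_o[k][ii, jj]
            den = conv_e[k][ii, jj]
            with np.errstate(invalid="ignore", divide="ignore"):
                lam_bal = np.where(den > 0, num / den, np.nan) * E[ii, jj]
            lam_raw = lam_bal * bias[ii] * bias[jj]
            ok = np.isfinite(lam_raw) & (lam_raw > 0)
            p = np.ones(len(ii))
            p[ok] = poisson.sf(np.round(raw_obs[ok]) - 1, lam_raw[ok])
            with np.errstate(invalid="ignore", divide="ignore"):
                fold = np.where(lam_bal > 0, bal[ii, jj] / lam_bal, np.inf)
            row[f"p_{k}"] = p
            row[f"fold_{k}"] = fold
        records.append(pd.DataFrame(row))

    if not records:
        return LoopSet(B, _empty_loops())
    cand = pd.concat(records, ignore_index=True)
    for k in ("donut", "lower_left"):
        cand[f"q_{k}"] = false_discovery_control(cand[f"p_{k}"].to_numpy(),
                                                 method="bh")
    sig = ((cand["q_donut"] <= q_max) & (cand["q_lower_left"] <= q_max))
    for k in _NEIGHBORHOODS:
        sig &= cand[f"fold_{k}"] >= fold_min
    sig_df = cand.loc[sig]

    merged = []
    for chrom, grp in sig_df.groupby("chrom", sort=False):
        nb = matrix.bins.n_bins(chrom)
        grid = np.zeros((nb, nb), dtype=bool)
        grid[grp["bin1"].to_numpy(), grp["bin2"].to_numpy()] = True
        labels, n_clust = ndimage.label(grid, structure=np.ones((3, 3)))
        lab_of = labels[grp["bin1"].to_numpy(), grp["bin2"].to_numpy()]
        grp = grp.assign(_lab=lab_of)
        for _, cluster in grp.groupby("_lab"):
            best = cluster.loc[cluster["obs"].idxmax()].drop(labels="_lab")
            merged.append(best)
    loops = (pd.DataFrame(merged).reset_index(drop=True) if merged
             else _empty_loops())
    if len(loops):
        loops = loops.sort_values(["chrom", "bin1", "bin2"]).reset_index(drop=True)
    return LoopSet(B, loops)


def _empty_loops() -> pd.DataFrame:
    cols = ["chrom", "bin1", "bin2", "obs"]
    cols += [f"p_{k}" for k in _NEIGHBORHOODS]
    cols += [f"fold_{k}" for k in _NEIGHBORHOODS]
    cols += ["q_donut", "q_lower_left"]
    return pd.DataFrame(columns=cols)


# ---------------------------------------------------------------------------
# APA
# ---------------------------------------------------------------------------

@dataclass
class ApaResult:
    """Aggregate O/E submatrix around anchor pixels.

    ``aggregate`` is (2W+1)^2 with row index increasing along bin1; the
    lower-left corner (large bin1, small bin2) is the short-distance
    background used for the score.
    """

    window: int
    corner: int
    aggregate: np.ndarray
    n_anchors: int
    n_skipped: int
    is_difference: bool = False
    score_diff: float | None = None

    @property
    def score(self) -> float:
        W, c = self.window, self.corner
        center = self.aggregate[W, W]
        corner = self.aggregate[2 * W - c + 1:, :c]
        return float(center / corner.mean())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.aggregate).to_csv(path, sep="\t", header=False,
                                            index=False)


def apa(oe_matrix: ContactMatrix, anchors, window: int = 5,
        corner: int = 3) -> ApaResult:
    """Aggregate peak analysis over O/E submatrices centered on anchors.

    Anchors closer than ``2*window`` bins to the diagonal or too close to the
    chromosome edge are skipped (and counted).  Cells that are NaN in some
    submatrices are averaged over the anchors where they are finite.
    """
    if oe_matrix.state != "oe":
        raise ValueError("apa expects an O/E-transformed matrix")
    g = oe_matrix.bins
    W = window
    acc = np.zeros((2 * W + 1, 2 * W + 1))
    cnt = np.zeros_like(acc)
    used = skipped = 0
    for chrom, i, j in anchors:
        nb = g.n_bins(chrom)
        if (j - i) <= 2 * W or i - W < 0 or j + W >= nb:
            skipped += 1
            continue
        block = oe_matrix.cis(chrom)[i - W:i + W + 1, j - W:j + W + 1]
        fin = np.isfinite(block)
        acc[fin] += block[fin]
        cnt += fin
        used += 1
    if used == 0:
        raise ValueError("no usable anchors for APA")
    with np.errstate(invalid="ignore"):
        agg = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return ApaResult(W, corner, agg, used, skipped)


def apa_vs_reference(sample: ApaResult, reference: ApaResult) -> ApaResult:
    """Cellwise difference of APA aggregates (sample minus reference)."""
    if sample.window != reference.window or sample.corner != reference.corner:
        raise ValueError("APA results have different geometry")
    return ApaResult(sample.window, sample.corner,
                     sample.aggregate - reference.aggregate,
                     sample.n_anchors, sample.n_skipped, is_difference=True,
                     score_diff=sample.score - reference.score)
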