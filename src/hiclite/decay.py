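"""Distance-decay analysis: Ps curves, LOWESS expected values, RCP, O/E.

Contact probability Ps is the mean cis interaction at each genomic separation,
accumulated in distance strata (1 Mb wide by default, matching the convention
of stratifying at 1 M, 2 M, 3 M, ...).  The expected value at a distance is
obtained by LOWESS regression of log(observed) on log(distance); the relative
contact probability (RCP) is the per-chromosome observed curve normalized to
unit sum so samples of different depth overlay directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .matrix import ContactMatrix

__all__ = ["DecayCurve", "decay_curve", "lowess_expected",
           "observed_over_expected"]


@dataclass
class DecayCurve:
    """Distance-stratified contact statistics.

    ``strata`` holds the representative distance of each stratum in bp
    (stratum s covers separations in [s*W, (s+1)*W) and is labelled
    (s+1)*W, i.e. 1 M, 2 M, ... for the default 1 Mb width).  ``observed``
    is the genome-wide mean interaction per stratum; ``per_chrom`` the
    per-chromosome equivalents; ``expected`` the LOWESS fit (filled by
    :func:`lowess_expected`); ``rcp`` maps chromosome -> unit-sum observed
    curve.
    """

    stratum_bp: float
    strata: np.ndarray          # stratum labels (upper edge), bp
    observed: np.ndarray        # genome-wide mean per stratum (NaN if empty)
    per_chrom: pd.DataFrame     # columns: chrom, stratum_bp_label, observed
    mean_dist: np.ndarray | None = None  # mean cell separation per stratum, bp
    expected: np.ndarray | None = None
    rcp: dict[str, np.ndarray] = field(default_factory=dict)
    lowess_frac: float | None = None

    def expected_at(self, distance_bp: np.ndarray) -> np.ndarray:
        """Expected value at arbitrary distances (stratum lookup, clamped)."""
        if self.expected is None:
            raise ValueError("expected curve not fitted; run lowess_expected")
        s = (np.asarray(distance_bp, dtype=float) // self.stratum_bp).astype(int)
        s = np.clip(s, 0, len(self.expected) - 1)
        return self.expected[s]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"distance": self.strata, "observed": self.observed})
        if self.expected is not None:
            df["expected"] = self.expected
        return df


def _stratum_sums(cis: np.ndarray, mask: np.ndarray, bin_size: int,
                  stratum_bp: float):
    """Per-stratum (sum, count) over unmasked upper-triangle cells."""
    nb = cis.shape[0]
    n_strata = int((nb - 1) * bin_size // stratum_bp) + 1
    sums = np.zeros(n_strata)
    counts = np.zeros(n_strata)
    dist_sums = np.zeros(n_strata)
    keep = ~mask
    for k in range(nb):
        diag = np.diagonal(cis, k)
        good = keep[:nb - k] & keep[k:]
        with np.errstate(invalid="ignore"):
            good = good & ~np.isnan(diag)
        if not good.any():
            continue
        s = int(k * bin_size // stratum_bp)
        sums[s] += diag[good].sum()
        counts[s] += good.sum()
        dist_sums[s] += good.sum() * k * bin_size
    return sums, counts, dist_sums


def decay_curve(matrix: ContactMatrix, stratum_bp: float = 1e6) -> DecayCurve:
    """Observed contact frequency per distance stratum (genome-wide and
    per chromosome), over unmasked cis cells."""
    g = matrix.bins
    B = g.bin_size
    stratum_bp = float(stratum_bp)
    if stratum_bp < B:
        raise ValueError("stratum width must be at least one bin")
    max_nb = max(g.n_bins(c) for c in g.chrom_names)
    n_strata = int((max_nb - 1) * B // stratum_bp) + 1
    tot_sum = np.zeros(n_strata)
    tot_cnt = np.zeros(n_strata)
    tot_dist = np.zeros(n_strata)
    rows = []
    rcp = {}
    for chrom in g.chrom_names:
        s, c, ds = _stratum_sums(matrix.cis(chrom), matrix.chrom_mask(chrom),
                                 B, stratum_bp)
        tot_sum[:len(s)] += s
        tot_cnt[:len(c)] += c
        tot_dist[:len(ds)] += ds
        with np.errstate(invalid="ignore", divide="ignore"):
            obs = np.where(c > 0, s / np.maximum(c, 1), np.nan)
        for k, v in enumerate(obs):
            rows.append((chrom, (k + 1) * stratum_bp, v))
        total = np.nansum(obs)
        rcp[chrom] = (np.nan_to_num(obs) / total if total > 0
                      else np.full_like(obs, np.nan))
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = np.where(tot_cnt > 0, tot_sum / np.maximum(tot_cnt, 1),
                            np.nan)
    strata = (np.arange(n_strata) + 1) * stratum_bp
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dist = np.where(tot_cnt > 0, tot_dist / np.maximum(tot_cnt, 1),
                             np.nan)
    per_chrom = pd.DataFrame(rows, columns=["chrom", "distance", "observed"])
    return DecayCurve(stratum_bp, strata, observed, per_chrom,
                      mean_dist=mean_dist, rcp=rcp)


def lowess_expected(curve: DecayCurve, frac: float = 0.3,
                    it: int = 2) -> DecayCurve:
    """Fill the expected part of a decay curve by LOWESS in log-log space.

    Fits locally weighted linear regression of log(observed) on log(distance)
    over strata with positive observed mean, evaluates at every stratum, and
    exponentiates — so expected values are strictly positive wherever defined.
    Falls back to the raw observed curve when fewer than 4 usable strata exist.
    """
    obs = curve.observed
    dist = (curve.mean_dist if curve.mean_dist is not None
            else curve.strata.astype(float))
    ok = np.isfinite(obs) & (obs > 0) & np.isfinite(dist) & (dist > 0)
    expected = np.full_like(obs, np.nan)
    if ok.sum() < 4:
        warnings.warn("fewer than 4 usable strata; expected = observed")
        fin = np.isfinite(obs) & (obs > 0)
        expected[fin] = obs[fin]
    else:
        x = np.log(dist[ok])
        y = np.log(obs[ok])
        fit = _lowess(y, x, frac=frac, it=it, return_sorted=False)
        vals = np.exp(fit)
        expected[ok] = vals
        # the zero-distance (diagonal) stratum keeps its observed mean
        diag = np.isfinite(obs) & (obs > 0) & ~ok
        expected[diag] = obs[diag]
        # strata with zero observed still need an expected value for O/E:
        # interpolate the fitted trend in log-log space
        missing = np.isfinite(obs) & ~np.isfinite(expected) & (dist > 0)
        if missing.any():
            expected[missing] = np.exp(
                np.interp(np.log(dist[missing]), x, np.log(vals)))
    curve.expected = expected
    curve.lowess_frac = frac
    return curve


def observed_over_expected(matrix: ContactMatrix,
                           curve: DecayCurve) -> ContactMatrix:
    """Divide each cis cell by the expected value at its distance.

    Cells whose expected value is zero/undefined, and masked bins, become
    NaN.  Trans blocks are set to NaN (O/E is a cis transform).
    """
    g = matrix.bins
    n = g.n_bins_total
    oe = np.full((n, n), np.nan)
    for chrom in g.chrom_names:
        s = g.chrom_slice(chrom)
        cis = matrix.counts[s, s]
        nb = cis.shape[0]
        d = np.abs(np.arange(nb)[:, None] - np.arange(nb)[None, :]) * g.bin_size
        exp = curve.expected_at(d.ravel()).reshape(nb, nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            block = np.where(exp > 0, cis / exp, np.nan)
        m = matrix.chrom_mask(chrom)
        block[m, :] = np.nan
        block[:, m] = np.nan
        oe[s, s] = block
    return ContactMatrix(g, oe, bias=matrix.bias.copy(),
                         mask=matrix.mask.copy(), state="oe",
                         total_pairs=matrix.total_pairs)
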