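"""A/B compartment analysis.

Compartments are called per chromosome from the leading eigenvector (E1) of
the Pearson correlation matrix of the O/E contact map.  The eigenvector sign
is arbitrary, so E1 is oriented against a per-bin covariate (gene density by
default: the A compartment is gene-rich), after which A = positive, B =
negative.  Group-wise switch detection finds runs of bins where every sample
of one group sits in A and every sample of the other in B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .genome import GenomeBins
from .matrix import ContactMatrix

__all__ = ["CompartmentTrack", "compartment_eigenvector", "orient_and_call",
           "detect_switches", "read_bed", "gene_density"]


@dataclass
class CompartmentTrack:
    """Per-bin leading-eigenvector values with A/B labels.

    ``e1`` is NaN at masked bins; ``labels`` holds 'A' (e1 > 0), 'B'
    (e1 < 0) or 'NA'.  ``explained`` maps chromosome to the leading
    eigenvalue's share of total (absolute) eigenvalue mass — a low share
    flags a map with little compartment signal.
    """

    bins: GenomeBins
    e1: np.ndarray
    labels: np.ndarray | None = None
    explained: dict[str, float] = field(default_factory=dict)
    oriented: bool = False
    covariate_name: str | None = None

    def relabel(self) -> None:
        lab = np.full(len(self.e1), "NA", dtype=object)
        lab[self.e1 > 0] = "A"
        lab[self.e1 < 0] = "B"
        self.labels = lab

    def to_bedgraph(self, path) -> None:
        tab = self.bins.bin_table()
        tab["e1"] = self.e1
        tab.dropna(subset=["e1"])[["chrom", "start", "end", "e1"]].to_csv(
            path, sep="\t", header=False, index=False)


def compartment_eigenvector(oe_matrix: ContactMatrix,
                            min_bins: int = 10) -> CompartmentTrack:
    """Leading eigenvector of the per-chromosome O/E correlation matrix.

    Chromosomes with fewer than ``min_bins`` unmasked bins are skipped
    (all-NaN).  Raises if no chromosome carries signal (e.g. a constant
    O/E map has no compartment structure to decompose).
    """
    g = oe_matrix.bins
    e1 = np.full(g.n_bins_total, np.nan)
    explained = {}
    any_signal = False
    for chrom in g.chrom_names:
        s = g.chrom_slice(chrom)
        block = oe_matrix.counts[s, s]
        keep = ~oe_matrix.chrom_mask(chrom)
        keep &= np.isfinite(block).sum(axis=0) > 0
        if keep.sum() < min_bins:
            continue
        sub = block[np.ix_(keep, keep)]
        sub = np.where(np.isfinite(sub), sub, 0.0)
        sd = sub.std(axis=0)
        live = sd > 0
        if live.sum() < min_bins:
            continue
        corr = np.corrcoef(sub[np.ix_(live, live)], rowvar=False)
        w, v = eigh(corr)
        lead = v[:, -1]
        share = float(w[-1] / np.abs(w).sum())
        full = np.full(block.shape[0], np.nan)
        idx = np.flatnonzero(keep)[live]
        full[idx] = lead
        e1[s] = full
        explained[chrom] = share
        any_signal = True
    if not any_signal:
        raise ValueError("no compartment signal: degenerate O/E matrix")
    track = CompartmentTrack(g, e1, explained=explained)
    track.relabel()
    return track


def orient_and_call(track: CompartmentTrack, covariate: np.ndarray,
                    name: str = "gene_density") -> CompartmentTrack:
    """Orient E1 so it correlates positively with the covariate, per
    chromosome, then assign A/B labels by sign."""
    cov = np.asarray(covariate, dtype=float)
    if len(cov) != len(track.e1):
        raise ValueError("covariate length does not match bins")
    e1 = track.e1.copy()
    for chrom in track.bins.chrom_names:
        s = track.bins.chrom_slice(chrom)
        seg, cseg = e1[s], cov[s]
        ok = np.isfinite(seg) & np.isfinite(cseg)
        if ok.sum() < 2:
            continue
        if ok.sum() < 0.5 * np.isfinite(seg).sum():
            warnings.warn(f"{chrom}: covariate defined on <50% of bins")
        if np.std(cseg[ok]) == 0 or np.std(seg[ok]) == 0:
            warnings.warn(f"{chrom}: constant covariate; orientation unchanged")
            continue
        if np.corrcoef(seg[ok], cseg[ok])[0, 1] < 0:
            e1[s] = -seg
    out = CompartmentTrack(track.bins, e1, explained=dict(track.explained),
                           oriented=True, covariate_name=name)
    out.relabel()
    return out


def detect_switches(tracks_group1: list[CompartmentTrack],
                    tracks_group2: list[CompartmentTrack],
                    min_run: int = 3,
                    genes: pd.DataFrame | None = None):
    """Group-consistent A/B switch regions (and the genes they touch).

    A bin switches when every group-1 sample has one E1 sign and every
    group-2 sample the opposite sign; runs of at least ``min_run``
    consecutive switching bins are merged into half-open bp regions.
    ``genes`` (BED-like frame: chrom, start, end, name) are reported when
    they overlap a region by >= 1 bp.

    Returns (regions, gene_hits) DataFrames.
    """
    if not tracks_group1 or not tracks_group2:
        raise ValueError("both groups need at least one track")
    g = tracks_group1[0].bins
    for t in tracks_group1 + tracks_group2:
        if not t.bins.same_bins(g):
            raise ValueError("tracks are on different bins")
    E1 = np.vstack([t.e1 for t in tracks_group1])
    E2 = np.vstack([t.e1 for t in tracks_group2])
    defined = np.isfinite(E1).all(axis=0) & np.isfinite(E2).all(axis=0)
    g1_pos = (E1 > 0).all(axis=0)
    g1_neg = (E1 < 0).all(axis=0)
    g2_pos = (E2 > 0).all(axis=0)
    g2_neg = (E2 < 0).all(axis=0)
    a_to_b = defined & g1_pos & g2_neg   # group1 A -> group2 B
    b_to_a = defined & g1_neg & g2_pos

    regions = []
    table = g.bin_table()
    for chrom in g.chrom_names:
        s = g.chrom_slice(chrom)
        for direction, flags in (("A->B", a_to_b[s]), ("B->A", b_to_a[s])):
            for start, stop in _runs(flags, min_run):
                start_bp = int(table.iloc[g.offset(chrom) + start]["start"])
                end_bp = int(table.iloc[g.offset(chrom) + stop - 1]["end"])
                regions.append((chrom, start_bp, end_bp, direction,
                                stop - start))
    regions = pd.DataFrame(
        regions, columns=["chrom", "start", "end", "direction", "n_bins"])

    hits = pd.DataFrame(columns=["chrom", "start", "end", "name",
                                 "region_start", "region_end"])
    if genes is not None and len(regions):
        out = []
        for _, r in regions.iterrows():
            sel = genes[(genes["chrom"] == r["chrom"])
                        & (genes["end"] > r["start"])
                        & (genes["start"] < r["end"])]
            for _, grow in sel.iterrows():
                out.append((grow["chrom"], grow["start"], grow["end"],
                            grow.get("name", "."), r["start"], r["end"]))
        if out:
            hits = pd.DataFrame(out, columns=hits.columns)
    return regions, hits


def _runs(flags: np.ndarray, min_run: int):
    """Yield (start, stop) half-open index ranges of True runs >= min_run."""
    padded = np.concatenate([[False], flags, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_run:
            yield int(start), int(stop)


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (first 4 columns used; name optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3].assign(name=".")
    df.columns = ["chrom", "start", "end", "name"][:df.shape[1]]
    if "name" not in df.columns:
        df["name"] = "."
    df["chrom"] = df["chrom"].astype(str)
    return df


def gene_density(genes: pd.DataFrame, bins: GenomeBins) -> np.ndarray:
    """Genes per bin (counted at the gene midpoint) — the default
    orientation covariate."""
    dens = np.zeros(bins.n_bins_total)
    for _, row in genes.iterrows():
        chrom = row["chrom"]
        if chrom not in bins.chromsizes:
            continue
        mid = (int(row["start"]) + int(row["end"])) // 2
        b = min(mid // bins.bin_size, bins.n_bins(chrom) - 1)
        dens[bins.offset(chrom) + b] += 1
    return dens
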