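"""End-to-end pipeline: from a sample sheet of valid-pairs files to the full
set of comparative outputs.

One :class:`RunConfig` (a plain YAML file) drives the whole workflow:

per sample
    binning at the analysis bin size -> ICE balancing -> resolution report ->
    distance-decay/RCP curves -> O/E -> compartments -> insulation/TADs ->
    loops;
across samples
    delta matrices against a reference, pairwise SCC matrix, APA anchored on
    the reference sample's calls with minus-reference differencing,
    group-wise compartment-switch detection, and joint-normalized exact-test
    differential interactions.

Everything is deterministic given the config; a JSON run report collects the
summary statistics and a manifest lists every written file with a checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compartments as cmod
from . import compare as xmod
from . import decay as dmod
from . import insulation as imod
from . import loops as lmod
from .genome import GenomeBins, read_chromsizes
from .matrix import (RESOLUTION_GRID, bin_contacts, ice_normalize,
                     cis_trans_summary, delta_matrix, map_resolution,
                     write_triplets)
from .pairs import read_valid_pairs

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_outputs"]

DEFAULT_BIN_SIZES = (20_000, 40_000, 150_000, 500_000, 1_000_000)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see package README for a sample)."""

    samples: list[dict]                 # each: name, path, group
    genome_path: str
    outdir: str
    bin_sizes: tuple = DEFAULT_BIN_SIZES
    analysis_bin_size: int | None = None   # default: min(bin_sizes)
    resolution_sizes: tuple = RESOLUTION_GRID
    resolution_threshold: int = 1000
    ice: dict = field(default_factory=lambda: dict(
        max_iter=100, low_pct=0.02, high_pct=0.0, eps=0.1))
    decay_stratum_bp: float = 1e6
    lowess_frac: float = 0.3
    insulation_window: int = 25
    boundary_strength_min: float = 0.1
    min_tad_bins: int = 3
    loops: dict = field(default_factory=lambda: dict(
        d_min=2, d_max_bp=2e6, donut_R=5, inner_r=2,
        fold_min=1.5, q_max=0.1))
    apa_window: int = 5
    apa_corner: int = 3
    scc_h: int = 2
    scc_max_distance_bp: float = 5e6
    switch_min_run: int = 3
    reference: str | None = None        # sample name; default first sample
    genes_bed: str | None = None
    seed: int = 0

    def validate(self) -> None:
        names = [s["name"] for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be unique")
        ref = self.reference or names[0]
        if ref not in names:
            raise ValueError(f"reference sample {ref!r} not in sheet")
        for s in self.samples:
            if not Path(s["path"]).exists():
                raise FileNotFoundError(s["path"])
        if not Path(self.genome_path).exists():
            raise FileNotFoundError(self.genome_path)

    @property
    def reference_name(self) -> str:
        return self.reference or self.samples[0]["name"]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _stage(stage: str, **params):
    logger.info("=== %s === %s", stage,
                " ".join(f"{k}={v}" for k, v in params.items()))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow; returns the in-memory results bundle.

    The bundle maps sample names to their per-sample results plus a
    "comparison" entry; :func:`write_outputs` serializes it.
    """
    config.validate()
    chromsizes = read_chromsizes(config.genome_path)
    B = config.analysis_bin_size or min(config.bin_sizes)
    genome = GenomeBins(chromsizes, B)
    genes = (cmod.read_bed(config.genes_bed)
             if config.genes_bed is not None else None)
    covariate = (cmod.gene_density(genes, genome) if genes is not None
                 else None)

    results = {"config": config, "samples": {}, "comparison": {}}
    for s in config.samples:
        name = s["name"]
        _stage("sample", name=name, bin_size=B)
        pairs = read_valid_pairs(s["path"], chromsizes)
        raw = bin_contacts(pairs, genome)
        raw_all = {bs: bin_contacts(pairs, GenomeBins(chromsizes, bs))
                   for bs in config.bin_sizes if bs != B}
        balanced = ice_normalize(raw, **config.ice)
        res_report = map_resolution(pairs, chromsizes,
                                    candidate_sizes=config.resolution_sizes,
                                    depth_threshold=config.resolution_threshold)
        ps_curve = dmod.lowess_expected(
            dmod.decay_curve(balanced, stratum_bp=config.decay_stratum_bp),
            frac=config.lowess_frac)
        fine_curve = dmod.lowess_expected(
            dmod.decay_curve(balanced, stratum_bp=B), frac=config.lowess_frac)
        oe = dmod.observed_over_expected(balanced, fine_curve)
        try:
            track = cmod.compartment_eigenvector(oe)
            if covariate is not None:
                track = cmod.orient_and_call(track, covariate)
        except ValueError:
            track = None
        ins = imod.insulation_score(balanced, window=config.insulation_window)
        tads = imod.call_boundaries_and_tads(
            ins, strength_min=config.boundary_strength_min,
            min_tad=config.min_tad_bins)
        loopset = lmod.call_loops(balanced, fine_curve, **config.loops)
        cis_means, trans_df = cis_trans_summary(balanced)
        results["samples"][name] = dict(
            group=s.get("group"), pairs=pairs, raw=raw, raw_other=raw_all,
            balanced=balanced, oe=oe, resolution=res_report,
            ps_curve=ps_curve, fine_curve=fine_curve, compartments=track,
            insulation=ins, tads=tads, loops=loopset,
            cis_means=cis_means, trans_summary=trans_df)

    # ---- cross-sample stages ---------------------------------------------
    names = [s["name"] for s in config.samples]
    ref = config.reference_name
    samp = results["samples"]
    if len(names) > 1:
        _stage("comparison", reference=ref, n_samples=len(names))
        deltas = {n: delta_matrix(samp[n]["balanced"], samp[ref]["balanced"])
                  for n in names if n != ref}
        scc_mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                r = xmod.scc(samp[names[a]]["balanced"],
                             samp[names[b]]["balanced"], h=config.scc_h,
                             max_distance_bp=config.scc_max_distance_bp).scc
                scc_mat.iloc[a, b] = scc_mat.iloc[b, a] = r

        anchors = samp[ref]["loops"].anchors()
        apa_results, apa_diffs = {}, {}
        if anchors:
            for n in names:
                try:
                    apa_results[n] = lmod.apa(samp[n]["oe"], anchors,
                                              window=config.apa_window,
                                              corner=config.apa_corner)
                except ValueError:
                    logger.warning("APA skipped for %s: no usable anchors", n)
            if ref in apa_results:
                apa_diffs = {n: lmod.apa_vs_reference(a, apa_results[ref])
                             for n, a in apa_results.items() if n != ref}

        groups = sorted({s.get("group") for s in config.samples
                         if s.get("group") is not None})
        switches = diff = None
        if len(groups) == 2:
            tracks = {gname: [samp[s["name"]]["compartments"]
                              for s in config.samples
                              if s.get("group") == gname]
                      for gname in groups}
            if all(t is not None for ts in tracks.values() for t in ts):
                switches = cmod.detect_switches(
                    tracks[groups[0]], tracks[groups[1]],
                    min_run=config.switch_min_run, genes=genes)
            # differential testing runs on raw counts: its joint loess
            # normalization replaces ICE, and balancing would smear a focal
            # group effect across the whole row
            g1 = [samp[s["name"]]["raw"] for s in config.samples
                  if s.get("group") == groups[0]]
            g2 = [samp[s["name"]]["raw"] for s in config.samples
                  if s.get("group") == groups[1]]
            normed = xmod.joint_normalize(g1 + g2, frac=config.lowess_frac)
            diff = xmod.exact_test_diff(normed[:len(g1)], normed[len(g1):])
        else:
            logger.info("fewer/more than 2 groups: switch and differential "
                        "stages skipped")
        results["comparison"] = dict(deltas=deltas, scc=scc_mat,
                                     apa=apa_results, apa_diff=apa_diffs,
                                     switches=switches, diff=diff,
                                     groups=groups)
    else:
        logger.info("single sample: comparison stages skipped")
    return results


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(results: dict, outdir) -> pd.DataFrame:
    """Serialize a results bundle; returns the file manifest (path, sha256)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(path: Path):
        written.append(path)

    report = {"samples": {}, "comparison": {}}
    for name, r in results["samples"].items():
        d = outdir / name
        d.mkdir(exist_ok=True)
        write_triplets(r["balanced"], d / "matrix.balanced.tsv",
                       d / "bins.tsv")
        _w(d / "matrix.balanced.tsv"); _w(d / "bins.tsv")
        r["resolution"].to_json(d / "resolution.json")
        _w(d / "resolution.json")
        r["ps_curve"].to_frame().to_csv(d / "decay.tsv", sep="\t", index=False)
        _w(d / "decay.tsv")
        rcp_rows = [(c, (k + 1) * r["ps_curve"].stratum_bp, v)
                    for c, arr in r["ps_curve"].rcp.items()
                    for k, v in enumerate(arr)]
        pd.DataFrame(rcp_rows, columns=["chrom", "distance", "rcp"]).to_csv(
            d / "rcp.tsv", sep="\t", index=False)
        _w(d / "rcp.tsv")
        if r["compartments"] is not None:
            r["compartments"].to_bedgraph(d / "e1.bedgraph")
            _w(d / "e1.bedgraph")
        r["insulation"].to_bedgraph(d / "insulation.bedgraph")
        _w(d / "insulation.bedgraph")
        r["tads"].to_bed(d / "tads.bed")
        _w(d / "tads.bed")
        r["loops"].to_bedpe(d / "loops.bedpe")
        _w(d / "loops.bedpe")
        report["samples"][name] = {
            "n_pairs": len(r["pairs"]),
            "finest_resolution": r["resolution"].finest_achieved,
            "n_tads": len(r["tads"].tads),
            "n_loops": len(r["loops"]),
            "cis_means": r["cis_means"],
            "n_flagged_trans": int(r["trans_summary"]["flagged"].sum()),
        }

    comp = results.get("comparison") or {}
    if comp:
        d = outdir / "comparison"
        d.mkdir(exist_ok=True)
        comp["scc"].to_csv(d / "scc_matrix.tsv", sep="\t")
        _w(d / "scc_matrix.tsv")
        for name, delta in comp["deltas"].items():
            write_triplets(delta, d / f"delta.{name}.tsv")
            _w(d / f"delta.{name}.tsv")
        for name, a in comp.get("apa", {}).items():
            a.to_tsv(d / f"apa.{name}.tsv")
            _w(d / f"apa.{name}.tsv")
        for name, a in comp.get("apa_diff", {}).items():
            a.to_tsv(d / f"apa_diff.{name}.tsv")
            _w(d / f"apa_diff.{name}.tsv")
        report["comparison"]["scc"] = comp["scc"].to_dict()
        report["comparison"]["apa_scores"] = {
            n: a.score for n, a in comp.get("apa", {}).items()}
        report["comparison"]["apa_score_diff"] = {
            n: a.score_diff for n, a in comp.get("apa_diff", {}).items()}
        if comp.get("switches") is not None:
            regions, genes_hit = comp["switches"]
            regions.to_csv(d / "switch_regions.bed", sep="\t", index=False,
                           header=False)
            _w(d / "switch_regions.bed")
            genes_hit.to_csv(d / "switch_genes.tsv", sep="\t", index=False)
            _w(d / "switch_genes.tsv")
            report["comparison"]["n_switch_regions"] = len(regions)
            report["comparison"]["n_switch_genes"] = int(
                genes_hit["name"].nunique()) if len(genes_hit) else 0
        if comp.get("diff") is not None:
            comp["diff"].to_tsv(d / "diff_table.tsv")
            _w(d / "diff_table.tsv")
            comp["diff"].md_composite().to_csv(d / "md_composite.tsv",
                                               sep="\t", index=False)
            _w(d / "md_composite.tsv")
            tab = comp["diff"].table
            top = tab.nsmallest(min(10, len(tab)), "q")
            report["comparison"]["n_significant_pixels"] = int(
                (tab["q"] < 0.05).sum())
            report["comparison"]["top_differential"] = top[
                ["chrom", "bin1", "bin2", "M", "q"]].to_dict("records")

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    _w(outdir / "report.json")

    manifest = pd.DataFrame(
        [(str(p.relative_to(outdir)), _sha256(p)) for p in written],
        columns=["path", "sha256"])
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
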