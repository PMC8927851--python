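# hiclite

Comparative Hi-C contact-map analysis at desk scale.

Hi-C experiments measure genome-wide chromatin contact frequencies between
pairs of loci. Comparing the resulting maps across individuals or cell types —
for example primary immune cells against a cell line, or patients against
controls — requires a chain of well-established steps: binning valid ligation
pairs into contact matrices, iterative-correction (ICE) balancing, determining
the usable map resolution from coverage, distance-decay (Ps/RCP) curves, A/B
compartment calling from the leading eigenvector of the O/E correlation
matrix, insulation-score TAD calling, HiCCUPS-style loop detection, aggregate
peak analysis (APA), hicrep-style stratum-adjusted correlation (SCC), and
multiHiCcompare-style differential interaction testing. `hiclite` implements
this whole chain as a tested Python library with a thin CLI, plus a synthetic
contact-map generator with planted ground truth (decay, compartments, TADs,
loops, replicate thinning, group effects) so that every stage can be validated
against structure that is known exactly.

## Core quantities

- **ICE balancing** — iteratively divides row/column *i* by its relative row
  sum until `max_i |s_i/mean(s) − 1| < ε` (defaults `MAX_ITER=100`,
  `FILTER_LOW_COUNT_PERC=0.02`, `EPS=0.1`); the accumulated divisor is the
  bias `b_i`.
- **Map resolution** — for each candidate bin size, sort per-bin end-coverage
  descending; the size is *achieved* when the depth at the 80th-percentile
  position reaches 1000.
- **Insulation** — `I_i = log2(s_i / ⟨s⟩)` with `s_i` the mean of the `w×w`
  window of contacts crossing bin *i*; boundaries are strong local minima.
- **Compartments** — sign of the leading eigenvector `E1` of the Pearson
  correlation of the per-chromosome O/E matrix, oriented by gene density
  (A = positive).
- **SCC** — `Σ_d w_d·r_d / Σ_d w_d` with `r_d` the Pearson correlation of the
  smoothed maps in distance stratum `d` and `w_d = N_d·sd(x_d)·sd(y_d)`.
- **Differential test** — joint cyclic-loess normalization of `log2(IF+0.5)`
  against distance, then an exact conditional test of each pixel's total
  split between groups (negative-binomial with stratum-level
  method-of-moments dispersion; binomial in the zero-dispersion limit),
  BH-corrected.

## Worked example

```python
import numpy as np
from hiclite import (SyntheticSpec, build_probability_map, sample_contacts,
                     thin_replicate, bin_contacts, ice_normalize,
                     insulation_score, call_boundaries_and_tads, scc)

# a 10 Mb toy chromosome at 40 kb bins with 8 planted TADs
spec = SyntheticSpec(
    {"chrA": 10_000_000}, 40_000, alpha=1.0,
    tad_boundaries={"chrA": [31, 62, 93, 124, 156, 187, 218]},
    tad_boost=2.0, total_pairs=2_000_000, trans_fraction=0.0)
pmap = build_probability_map(spec)
parent = sample_contacts(pmap, spec.total_pairs, seed=1)

# two half-depth technical replicates and their reproducibility
rep1 = bin_contacts(thin_replicate(parent, 0.5, seed=2), spec.genome)
rep2 = bin_contacts(thin_replicate(parent, 0.5, seed=3), spec.genome)
print(f"SCC(rep1, rep2) = {scc(rep1, rep2).scc:.4f}")

# TAD boundaries from the insulation score of the balanced map
balanced = ice_normalize(bin_contacts(parent, spec.genome))
track = insulation_score(balanced, window=10)
tads = call_boundaries_and_tads(track)
print("planted boundaries:", spec.tad_boundaries["chrA"])
print("called  boundaries:", sorted(tads.boundaries["bin"]))
```

prints

```
SCC(rep1, rep2) = 0.9905
planted boundaries: [31, 62, 93, 124, 156, 187, 218]
called  boundaries: [31, 61, 93, 123, 155, 187, 217]
```

Two binomially thinned replicates of one library are nearly perfectly
reproducible (SCC ≈ 0.99, comfortably above the ≥ 0.97 expected of true
replicates), and every planted TAD boundary is recovered within one bin.

The full multi-sample workflow runs from a YAML config:

```sh
hiclite simulate --chrom-size chrA:10000000 --bin-size 40000 \
    --n-tads 8 --tad-boost 2 --n-per-group 2 --effect-factor 3 \
    --seed 7 --outdir cohort/
hiclite run-all --config run.yaml
```

producing, per sample, balanced triplet matrices, resolution reports,
decay/RCP tables, E1 and insulation bedGraphs, TAD BEDs and loop BEDPEs, and,
across samples, delta matrices, an SCC heat-table, APA aggregates with
minus-reference differences, compartment switch regions with gene annotation,
a differential-interaction table and MD-composite export — plus a JSON run
report and a checksummed manifest.

## Acceptance benchmarks

`scripts/acceptance.py` regenerates the package's two headline simulation
benchmarks from scratch — the minimum replicate SCC over ten seeded
thinning experiments (t1) and the percentage of 5 kb bins above the
depth-1000 threshold in the resolution analysis of a uniform-coverage
simulation (t2) — and writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for models, parameter choices and limitations.
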