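"""Shared fixtures: small synthetic worlds with planted structure.

Session scope keeps the expensive sampled maps to one build each; every
fixture is seeded so the suite is fully deterministic.
"""

import numpy as np
import pytest

from hiclite import (
    GenomeBins, SyntheticSpec, bin_contacts, build_probability_map,
    ice_normalize, sample_contacts, decay_curve, lowess_expected,
)


@pytest.fixture(scope="session")
def toy_genome():
    return GenomeBins({"chrA": 10_000_000, "chrB": 6_000_000}, 40_000)


@pytest.fixture(scope="session")
def tad_spec():
    """10 Mb chromosome, 40 kb bins, 8 equal TADs with boost 2."""
    nb = 250
    boundaries = [k * (nb // 8) for k in range(1, 8)]  # 31-ish spacing
    return SyntheticSpec({"chrA": nb * 40_000}, 40_000, alpha=1.0,
                         tad_boundaries={"chrA": boundaries}, tad_boost=2.0,
                         total_pairs=2_000_000, trans_fraction=0.0)


@pytest.fixture(scope="session")
def tad_matrix(tad_spec):
    """Balanced matrix sampled from the 8-TAD world (seed 101)."""
    pm = build_probability_map(tad_spec)
    pairs = sample_contacts(pm, tad_spec.total_pairs, 101)
    return ice_normalize(bin_contacts(pairs, tad_spec.genome))


@pytest.fixture(scope="session")
def checkerboard_spec():
    """100-bin chromosome with alternating 5-bin A/B blocks, strength 0.4."""
    lab = np.repeat(np.resize([1, -1], 20), 5)
    return SyntheticSpec({"chrA": 100 * 100_000}, 100_000, alpha=1.0,
                         compartment_labels={"chrA": lab},
                         compartment_strength=0.4,
                         total_pairs=1_000_000, trans_fraction=0.0)


@pytest.fixture(scope="session")
def checkerboard_oe(checkerboard_spec):
    from hiclite import observed_over_expected
    pm = build_probability_map(checkerboard_spec)
    pairs = sample_contacts(pm, checkerboard_spec.total_pairs, 202)
    bal = ice_normalize(bin_contacts(pairs, checkerboard_spec.genome))
    curve = lowess_expected(decay_curve(bal, stratum_bp=100_000))
    return checkerboard_spec, observed_over_expected(bal, curve)


@pytest.fixture(scope="session")
def loop_spec():
    """200-bin chromosome with four planted loops, boost 5."""
    loops = [("chrA", 30, 60), ("chrA", 50, 90), ("chrA", 80, 120),
             ("chrA", 140, 160)]
    return SyntheticSpec({"chrA": 200 * 40_000}, 40_000, alpha=1.0,
                         loops=loops, loop_boost=5.0, loop_halfwidth=1,
                         total_pairs=3_000_000, trans_fraction=0.0)


@pytest.fixture(scope="session")
def loop_balanced(loop_spec):
    pm = build_probability_map(loop_spec)
    pairs = sample_contacts(pm, loop_spec.total_pairs, 303)
    bal = ice_normalize(bin_contacts(pairs, loop_spec.genome))
    curve = lowess_expected(decay_curve(bal, stratum_bp=40_000))
    return loop_spec, bal, curve


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
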