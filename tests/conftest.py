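"""Shared fixtures: small synthetic studies generated at test time."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from mirdel import simulate as sim
from mirdel.quantify import quantify


@pytest.fixture(scope="session")
def tiny_config() -> sim.SimulationConfig:
    """Small reference: 10 hairpins (some with both arms) on short contigs."""
    return sim.SimulationConfig(
        n_control=2,
        n_case=2,
        n_mirnas=10,
        contig_lengths={"chrA": 9_000, "chrB": 7_000},
        deletion_interval=("chrA", 1_001, 4_000),
        mean_expression=(math.log(60.0), 0.8),
        two_mature_fraction=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_ref(tiny_config) -> sim.ToyReference:
    return sim.build_toy_reference(tiny_config)


@pytest.fixture(scope="session")
def error_free_run(tmp_path_factory):
    """Error-free study (no errors, no adapterless reads) and its pipeline result.

    isomiR offsets and background reads stay on: neither breaks exact count
    recovery, so this fixture also exercises the end-offset rule.
    """
    config = sim.SimulationConfig(
        n_control=3,
        n_case=3,
        n_mirnas=12,
        contig_lengths={"chrA": 12_000, "chrB": 8_000},
        deletion_interval=("chrA", 1_001, 5_000),
        mean_expression=(math.log(70.0), 0.8),
        error_rate=0.0,
        adapterless_fraction=0.0,
        background_fraction=0.1,
        two_mature_fraction=0.5,
        seed=13,
    )
    ref = sim.build_toy_reference(config)
    truth = sim.simulate_counts(ref, config)
    outdir = tmp_path_factory.mktemp("error_free")
    paths = sim.synthesize_reads(truth, ref, config, outdir)
    result = quantify(paths, ref)
    return config, ref, truth, paths, result


@pytest.fixture()
def null_counts():
    """NB counts with no group difference: 9 vs 7 libraries."""

    def make(n_genes: int, alpha: float, seed: int, mean_loc: float = math.log(400.0)):
        rng = np.random.default_rng(seed)
        means = np.exp(rng.normal(mean_loc, 1.2, n_genes))
        sf = np.exp(rng.normal(0.0, 0.15, 16))
        counts = sim.simulate_count_matrix(means, np.ones(n_genes), 9, 7, alpha, sf, rng)
        samples = [f"c{i}" for i in range(9)] + [f"p{i}" for i in range(7)]
        df = pd.DataFrame(counts, columns=samples)
        groups = pd.Series(["control"] * 9 + ["case"] * 7, index=samples)
        return df, groups

    return make
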