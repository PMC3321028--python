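"""Shared fixtures: packaged models and the default planted-truth genome."""

from __future__ import annotations

import numpy as np
import pytest

from nlrforge import PipelineConfig, SyntheticSpec, generate_genome, run_pipeline
from nlrforge import profile_hmm as hm
from nlrforge.resources import seed_alignment


@pytest.fixture(scope="session")
def nbarc_hmm():
    """Calibrated NB-ARC seed profile (shared; calibration is the slow part)."""
    hmm = hm.build_profile(list(seed_alignment("nbarc")), name="nbarc_seed")
    hm.calibrate_evalue(hmm, n_null=1000, null_length=350, seed=11)
    return hmm


@pytest.fixture(scope="session")
def kinase_hmm():
    hmm = hm.build_profile(list(seed_alignment("kinase")), name="kinase")
    hm.calibrate_evalue(hmm, n_null=500, null_length=350, seed=12)
    return hmm


@pytest.fixture(scope="session")
def default_genome():
    """The packaged study-condition genome: 60 NLRs over all 8 classes, 40%
    pseudogenes, 40 kinase decoys, 200 background genes, seed 7."""
    return generate_genome(SyntheticSpec())


@pytest.fixture(scope="session")
def default_result(default_genome):
    """Full pipeline run on the default genome (shared across tests)."""
    import time

    t0 = time.monotonic()
    res = run_pipeline(default_genome, PipelineConfig(seed=0))
    res.elapsed_seconds = time.monotonic() - t0
    return res


@pytest.fixture(scope="session")
def small_genome():
    """A reduced genome for fast pipeline-level tests."""
    return generate_genome(SyntheticSpec(
        class_counts={"CNL": 4, "CN": 2, "NL_CC": 2, "N_CC": 1,
                      "TNL": 2, "TN": 1, "NL_TIR": 0, "N_TIR": 1},
        n_clusters=2,
        n_kinase_decoys=6,
        n_background_genes=30,
        n_nbs_derived=1,
        n_partial_nbs=1,
        seed=21,
    ))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
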