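"""Shared fixtures.

The two expensive fixtures are session-scoped: the full staged hypothesis
test on the noisy synthetic reference study, and the noiseless ground-truth
recovery fit.  Both are deterministic (fixed seeds) and shared by the unit
and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import beigeflux as bf
from beigeflux.config import RunConfig
from beigeflux.synth import NoiseModel


@pytest.fixture(scope="session")
def catalog():
    return bf.build_standard_protocols()


@pytest.fixture(scope="session")
def truth():
    return bf.default_truth("H3")


@pytest.fixture(scope="session")
def study():
    """Noisy synthetic reference study at the default seed."""
    return bf.generate_study(bf.default_truth("H3"), NoiseModel(seed=0))


@pytest.fixture(scope="session")
def reference_report(study):
    """Full staged hypothesis test (stage A, stage B, discrimination,
    held-out validation) on the reference study.  Takes a few minutes."""
    stage_a, stage_b, val = bf.split_stages(study)
    vexp = next(iter(val.experiments.values()))
    cfg = RunConfig(seed=0)
    return bf.run_hypothesis_test(
        stage_a, stage_b, cfg, validation_data=(vexp.protocol, vexp.trace)
    )


@pytest.fixture(scope="session")
def noiseless_recovery(truth):
    """H3 fit to noiseless data generated from the H3 truth, with its
    acceptable-parameter ensemble."""
    stage_a, _, _ = bf.split_stages(
        bf.generate_study(truth, NoiseModel(sd_rel=0.0, sd_abs=0.0, seed=0))
    )
    cfg = RunConfig(seed=0, n_starts=1)
    hyp = bf.build_hypothesis("H3", cfg)
    fit = bf.fit_hypothesis(stage_a, hyp, cfg)
    ens = bf.collect_ensemble(stage_a, hyp, fit, cfg)
    return {"dataset": stage_a, "config": cfg, "hypothesis": hyp, "fit": fit,
            "ensemble": ens}
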