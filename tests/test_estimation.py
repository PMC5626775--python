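"""χ² machinery, fitting, ensembles and prediction bands."""

import numpy as np
import pytest

import beigeflux as bf
from beigeflux.config import RunConfig
from beigeflux.estimation import (
    AlignmentError,
    Dataset,
    DataError,
    Experiment,
    ParameterSpace,
    chi2_cost,
    chi2_threshold,
    collect_ensemble,
    fit_hypothesis,
    prediction_band,
)
from beigeflux.io import OCRTrace
from beigeflux.model import FREE_SHARED_PARAMETERS, ModelParameters, simulate_protocol
from beigeflux.synth import NoiseModel, split_stages


def _trace(mean, sem, times=None, eid="d"):
    times = times if times is not None else np.arange(len(mean), dtype=float) * 7
    return OCRTrace(eid, "control", "P0", times, np.asarray(mean, float),
                    np.asarray(sem, float))


class TestChi2:
    def test_zero_iff_identical(self):
        d = _trace([10, 12], [1, 2])
        assert chi2_cost(d.with_values(), d) == 0.0

    def test_unit_residuals_sum_to_n(self):
        d = _trace([10.0, 12.0, 8.0], [1.0, 2.0, 0.5])
        sim = d.with_values(mean=d.ocr_mean + d.ocr_sem)
        assert chi2_cost(sim, d) == pytest.approx(3.0)

    def test_worked_example(self):
        data = _trace([10.0, 12.0], [1.0, 2.0])
        sim = _trace([11.0, 16.0], [0.0, 0.0], eid="s")
        assert chi2_cost(sim, data) == pytest.approx(5.0)

    def test_grid_mismatch_and_bad_sem(self):
        with pytest.raises(AlignmentError):
            chi2_cost(_trace([1, 2], [1, 1]), _trace([1, 2, 3], [1, 1, 1]))
        with pytest.raises(DataError):
            chi2_cost(_trace([1, 2], [0, 0], eid="s"), _trace([1, 2], [0.0, 1.0]))

    def test_threshold_against_published_quantiles(self):
        assert chi2_threshold(1, 0.05) == pytest.approx(3.841, abs=1e-3)
        assert chi2_threshold(10, 0.05) == pytest.approx(18.307, abs=1e-3)

    def test_threshold_increases_with_df(self):
        ts = [chi2_threshold(df) for df in (1, 5, 20, 120)]
        assert ts == sorted(ts) and len(set(ts)) == len(ts)

    def test_threshold_domain_errors(self):
        with pytest.raises(ValueError):
            chi2_threshold(0)
        with pytest.raises(ValueError):
            chi2_threshold(5, alpha=1.5)


class TestParameterSpace:
    def test_default_space_counts_shared_and_modifiers(self):
        hyp = bf.build_hypothesis("H3")
        space = ParameterSpace(hyp, ["control", "rosi", "bmp4"], ModelParameters())
        kinds = [e.kind for e in space.entries]
        assert kinds.count("shared") == len(FREE_SHARED_PARAMETERS) == 20
        # rosi: u_ucp1, m_mito, f_ffa; bmp4: m_mito, f_ffa, u_alt
        assert kinds.count("mod") == 6

    def test_round_trip_decode_of_default_start(self):
        hyp = bf.build_hypothesis("H3")
        space = ParameterSpace(hyp, ["control", "rosi", "bmp4"], ModelParameters())
        params, mods = space.decode(space.x0)
        for n in FREE_SHARED_PARAMETERS:
            assert getattr(params, n) == pytest.approx(getattr(ModelParameters(), n), rel=1e-12)
        assert mods["control"].u_ucp1 == 0.0 and mods["control"].m_mito == 1.0

    def test_detection_limit_coupling(self):
        cfg = RunConfig(delta_detect_frac=0.1)
        hyp = bf.build_hypothesis("H2", cfg)
        space = ParameterSpace(hyp, ["control", "rosi", "bmp4"], ModelParameters())
        x = space.x0.copy()
        _, mods = space.decode(x)
        # theta starts at 1: bmp4 UCP1 = frac * rosi level exactly
        assert mods["bmp4"].u_ucp1 == pytest.approx(0.1 * mods["rosi"].u_ucp1)


@pytest.fixture(scope="module")
def tiny_dataset(truth, catalog):
    """Two noiseless experiments; enough to exercise the machinery fast."""
    ds = Dataset(provenance={"kind": "synthetic", "seed": 0})
    for cond in ("control", "rosi"):
        tr = bf.generate_trace(
            truth, cond, catalog["P0"], NoiseModel(sd_rel=0, sd_abs=0)
        )
        ds.add(Experiment(trace=tr, protocol=catalog["P0"], condition_id=cond))
    return ds


class TestFitting:
    def test_cost_decomposes_over_experiments(self, truth, catalog, tiny_dataset):
        cfg = RunConfig(n_starts=1, max_nfev=1)
        fit = fit_hypothesis(tiny_dataset, bf.build_hypothesis("H3", cfg), cfg)
        # recompute each experiment's cost from scratch and compare the sum
        total = 0.0
        for e in tiny_dataset.experiments.values():
            sim = simulate_protocol(
                fit.best_params, fit.best_mods[e.condition_id], e.protocol,
                rtol=cfg.rtol, atol=cfg.atol,
            )
            sem = np.maximum(e.trace.ocr_sem,
                             np.maximum(cfg.sem_floor, cfg.sem_floor_rel * np.abs(e.trace.ocr_mean)))
            total += chi2_cost(sim, e.trace.with_values(sem=sem))
        assert total == pytest.approx(fit.best_cost, rel=1e-9, abs=1e-9)

    def test_reproducible_given_seed(self, tiny_dataset):
        cfg = RunConfig(n_starts=2, max_nfev=60, seed=7)
        h = bf.build_hypothesis("H3", cfg)
        a = fit_hypothesis(tiny_dataset, h, cfg)
        b = fit_hypothesis(tiny_dataset, h, cfg)
        assert a.best_cost == b.best_cost
        assert np.array_equal(a.x_best, b.x_best)

    def test_inflated_sem_makes_any_model_acceptable(self, truth, catalog):
        ds = Dataset()
        tr = bf.generate_trace(truth, "rosi", catalog["P0"], NoiseModel(seed=3))
        big = tr.with_values(sem=tr.ocr_sem * 1000.0)
        ds.add(Experiment(trace=big, protocol=catalog["P0"], condition_id="rosi"))
        cfg = RunConfig(n_starts=1, max_nfev=2, sem_floor=0.0, sem_floor_rel=0.0)
        fit = fit_hypothesis(ds, bf.build_hypothesis("H3", cfg), cfg)
        assert fit.best_cost < 1.0 and not fit.rejected

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            fit_hypothesis(Dataset(), bf.build_hypothesis("H3"))


class TestEnsembleAndBand:
    def test_noiseless_truth_recovery_is_acceptable(self, noiseless_recovery):
        fit = noiseless_recovery["fit"]
        assert fit.best_cost <= fit.threshold
        assert not fit.rejected

    def test_best_fit_is_always_a_member(self, noiseless_recovery):
        ens = noiseless_recovery["ensemble"]
        fit = noiseless_recovery["fit"]
        assert any(np.array_equal(x, fit.x_best) for x, _ in ens.members)

    def test_members_pass_threshold_by_independent_reevaluation(self, noiseless_recovery):
        """Every sampled member, re-simulated from scratch, satisfies the χ²
        bound its ensemble claims."""
        ens = noiseless_recovery["ensemble"]
        ds = noiseless_recovery["dataset"]
        cfg = noiseless_recovery["config"]
        take = ens.members[:: max(1, len(ens.members) // 20)]
        for x, recorded in take:
            params, mods = ens.space.decode(x)
            total = 0.0
            for e in ds.experiments.values():
                sim = simulate_protocol(params, mods[e.condition_id], e.protocol,
                                        rtol=cfg.rtol, atol=cfg.atol)
                sem = np.maximum(e.trace.ocr_sem,
                                 np.maximum(cfg.sem_floor,
                                            cfg.sem_floor_rel * np.abs(e.trace.ocr_mean)))
                total += chi2_cost(sim, e.trace.with_values(sem=sem))
            assert total == pytest.approx(recorded, rel=1e-6, abs=1e-6)
            assert total <= ens.threshold * (1 + 1e-9)

    def test_rejected_fit_yields_empty_flagged_ensemble(self, truth, catalog):
        ds = Dataset()
        tr = bf.generate_trace(truth, "rosi", catalog["P2"], NoiseModel(seed=1))
        ds.add(Experiment(trace=tr, protocol=catalog["P2"], condition_id="rosi"))
        cfg = RunConfig(n_starts=1, max_nfev=1)
        hyp = bf.build_hypothesis("H3", cfg)
        fit = fit_hypothesis(ds, hyp, cfg)
        fit.rejected = True  # force the rejected path
        ens = collect_ensemble(ds, hyp, fit, cfg)
        assert len(ens) == 0 and ens.flag_undersized

    def test_two_member_band_is_pointwise_min_max(self, noiseless_recovery, catalog):
        import dataclasses

        ens = noiseless_recovery["ensemble"]
        two = dataclasses.replace(ens, members=ens.members[:2])
        band = prediction_band(two, "rosi", catalog["P0"])
        sims = []
        for x, _ in two.members:
            params, mods = ens.space.decode(x)
            sims.append(simulate_protocol(params, mods["rosi"], catalog["P0"],
                                          rtol=1e-6, atol=1e-8).ocr_mean)
        arr = np.vstack(sims)
        assert np.array_equal(band.lower, arr.min(axis=0))
        assert np.array_equal(band.upper, arr.max(axis=0))

    def test_single_member_band_has_zero_width(self, noiseless_recovery, catalog):
        import dataclasses

        ens = noiseless_recovery["ensemble"]
        one = dataclasses.replace(ens, members=ens.members[:1])
        band = prediction_band(one, "control", catalog["P0"])
        assert np.array_equal(band.lower, band.upper)
        assert np.array_equal(band.best, band.lower)

    def test_empty_ensemble_band_raises(self, noiseless_recovery, catalog):
        import dataclasses

        empty = dataclasses.replace(noiseless_recovery["ensemble"], members=[])
        with pytest.raises(ValueError):
            prediction_band(empty, "rosi", catalog["P0"])


def test_study_split_shapes(study):
    stage_a, stage_b, val = split_stages(study)
    assert len(stage_a) == 9 and len(stage_b) == 1 and len(val) == 1
    assert stage_a.n_points == 108
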