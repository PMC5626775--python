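"""Unit and property tests for the bioenergetics flux model and integrator."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import beigeflux as bf
from beigeflux.model import (
    AGENTS,
    ConditionModifiers,
    ModelParameters,
    StateVector,
    SteadyStateError,
    compute_fluxes,
    simulate_protocol,
    steady_state,
)


def unit_params():
    """All parameters 1 (n_alt=1); a minimal hand-checkable configuration."""
    return ModelParameters(**{n: 1.0 for n in ModelParameters.field_names()})


def reference_fluxes(dp, ffa, e, p: ModelParameters, m: ConditionModifiers):
    """Independent spreadsheet-style evaluation of the flux equations.

    Written directly from the model definitions with plain numpy, separately
    from the implementation's kernel.
    """
    v_etc = m.m_mito * p.k_etc * (1 + p.s_ffa * ffa) * (1 - e["rot_aa"]) / (1 + dp / p.K_dp)
    v_atp = m.m_mito * p.k_atp * dp * (1 - e["oligomycin"])
    act = m.u_ucp1 * (p.a0 + p.a_ffa * ffa + p.a_ra * e["atra"])
    hill = ffa ** p.n_alt / (p.K_alt ** p.n_alt + ffa ** p.n_alt) if ffa > 0 else 0.0
    return {
        "v_etc": v_etc,
        "v_atp": v_atp,
        "v_leak_basal": m.m_mito * p.L_basal * dp,
        "v_leak_ucp1": m.m_mito * p.L_ucp1 * act * dp,
        "v_leak_alt": m.m_mito * p.L_alt * m.u_alt * hill * dp,
        "v_leak_dnp": m.m_mito * p.L_dnp * e["dnp"] * dp,
        "ocr_total": v_etc + p.ocr_nonmito,
    }


class TestComputeFluxes:
    def test_complete_etc_inhibition_leaves_only_nonmito(self):
        p = ModelParameters()
        st_ = StateVector(dp=1.3, ffa=0.7, e={"rot_aa": 1.0})
        fx = compute_fluxes(st_, p, ConditionModifiers())
        assert fx.v_etc == 0.0
        assert fx.ocr_total == p.ocr_nonmito

    def test_zero_proton_motive_force_zeroes_atp_and_leak(self):
        fx = compute_fluxes(
            StateVector(dp=0.0, ffa=2.0),
            ModelParameters(),
            ConditionModifiers("rosi", u_ucp1=1.0, u_alt=0.5),
        )
        assert fx.v_atp == 0.0
        assert fx.v_leak == 0.0

    def test_unit_parameter_hand_arithmetic(self):
        # with everything at 1 and UCP1/alt absent: v_etc = 1*1*2*1/2 = 1,
        # v_atp = 1, basal leak = 1, total OCR = v_etc + nonmito = 2
        fx = compute_fluxes(
            StateVector(dp=1.0, ffa=1.0), unit_params(), ConditionModifiers()
        )
        assert fx.v_etc == pytest.approx(1.0, abs=1e-15)
        assert fx.v_atp == pytest.approx(1.0, abs=1e-15)
        assert fx.v_leak_basal == pytest.approx(1.0, abs=1e-15)
        assert fx.ocr_total == pytest.approx(2.0, abs=1e-15)

    def test_matches_independent_arithmetic_on_random_points(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            vals = {n: float(10 ** rng.uniform(-1, 1)) for n in ModelParameters.field_names()}
            vals["n_alt"] = float(rng.uniform(1, 3))
            p = ModelParameters(**vals)
            m = ConditionModifiers(
                "bmp4",
                u_ucp1=float(rng.uniform(0, 2)),
                m_mito=float(rng.uniform(0.5, 2)),
                f_ffa=float(rng.uniform(0.5, 2)),
                u_alt=float(rng.uniform(0, 2)),
            )
            state = StateVector(
                dp=float(rng.uniform(0, 3)),
                ffa=float(rng.uniform(0, 3)),
                e={a: float(rng.uniform(0, 1)) for a in AGENTS},
            )
            fx = compute_fluxes(state, p, m)
            ref = reference_fluxes(state.dp, state.ffa, state.e, p, m)
            for k, v in ref.items():
                got = getattr(fx, k)
                assert got == pytest.approx(v, rel=1e-10, abs=1e-12), k

    def test_negative_inputs_name_the_offending_field(self):
        with pytest.raises(ValueError, match="k_etc"):
            ModelParameters(k_etc=-1.0)
        with pytest.raises(ValueError, match="dp"):
            StateVector(dp=-0.1)
        with pytest.raises(ValueError, match="u_alt"):
            ConditionModifiers("bmp4", u_alt=-2.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        dp=st.floats(0, 10),
        ffa=st.floats(0, 10),
        e_dnp=st.floats(0, 1),
        e_oligo=st.floats(0, 1),
    )
    def test_ocr_ceiling(self, dp, ffa, e_dnp, e_oligo):
        """Total OCR never exceeds the substrate-driven ETC maximum."""
        p = ModelParameters()
        m = ConditionModifiers("rosi", u_ucp1=1.0, m_mito=1.5, f_ffa=1.5)
        fx = compute_fluxes(
            StateVector(dp=dp, ffa=ffa, e={"dnp": e_dnp, "oligomycin": e_oligo}), p, m
        )
        ceiling = m.m_mito * p.k_etc * (1 + p.s_ffa * ffa) + p.ocr_nonmito
        assert fx.ocr_total <= ceiling + 1e-9


class TestSteadyState:
    def test_no_ffa_source_gives_zero_ffa(self):
        p = ModelParameters(k_ffa0=0.0, k_lip=0.0, k_palm=0.0)
        assert steady_state(p, ConditionModifiers()).ffa == 0.0

    def test_full_etc_inhibition_gives_nonmito_ocr(self):
        p = ModelParameters(ocr_nonmito=0.0)
        s = steady_state(p, ConditionModifiers(), held_agents={"rot_aa"})
        fx = compute_fluxes(s, p, ConditionModifiers())
        assert fx.ocr_total == pytest.approx(0.0, abs=1e-9)

    def test_matches_bisection_oracle(self):
        """Δp at rest equals the root located by plain interval bisection."""
        p = ModelParameters()
        for mods in (
            ConditionModifiers(),
            ConditionModifiers("rosi", u_ucp1=1.0, m_mito=1.5, f_ffa=1.5),
            ConditionModifiers("bmp4", m_mito=1.3, f_ffa=2.0, u_alt=1.0),
        ):
            ffa = mods.f_ffa * p.k_ffa0 / p.k_clr

            def balance(dp):
                fx = compute_fluxes(StateVector(dp=dp, ffa=ffa), p, mods)
                return fx.v_etc - fx.v_atp - fx.v_leak

            lo, hi = 0.0, 10.0 * p.K_dp
            assert balance(lo) > 0 > balance(hi)
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if balance(mid) > 0:
                    lo = mid
                else:
                    hi = mid
            dp_oracle = 0.5 * (lo + hi)
            s = steady_state(p, mods)
            assert s.dp == pytest.approx(dp_oracle, rel=1e-6)

    def test_residual_contract(self):
        p = ModelParameters()
        s = steady_state(p, ConditionModifiers())
        fx = compute_fluxes(s, p, ConditionModifiers())
        assert abs(fx.v_etc - fx.v_atp - fx.v_leak) / fx.v_etc < 1e-9

    def test_unknown_held_agent_rejected(self):
        with pytest.raises(ValueError, match="unknown agent"):
            steady_state(ModelParameters(), ConditionModifiers(), {"fccp"})


class TestSimulateProtocol:
    def test_empty_protocol_is_flat_at_baseline(self, truth):
        proto = bf.Protocol(
            protocol_id="flat", events=[], measurement_times=[0, 7, 14, 21]
        )
        tr = simulate_protocol(truth.params, truth.mods("rosi"), proto)
        assert np.allclose(tr.ocr_mean, tr.ocr_mean[0], rtol=1e-6)
        assert np.all(tr.ocr_sem == 0)

    def test_rot_aa_drives_ocr_to_nonmito(self, truth):
        p = truth.params
        times = list(np.arange(0.0, 7 * p.tau_drug * 10, 7.0))
        proto = bf.Protocol(
            protocol_id="rot_only",
            events=[bf.InjectionEvent(0.0, "rot_aa")],
            measurement_times=times,
        )
        tr = simulate_protocol(p, truth.mods("control"), proto)
        assert tr.ocr_mean[-1] == pytest.approx(p.ocr_nonmito, rel=0.01)

    def test_stress_test_phase_ordering_and_cross_integrator(self, truth, catalog):
        """DNP raises OCR above basal, oligomycin lowers it below basal, and
        the default integrator agrees with an independent stiff re-run at
        10x tighter tolerance."""
        tr = simulate_protocol(truth.params, truth.mods("rosi"), catalog["P1"])
        basal, oligo, dnp = tr.ocr_mean[1], tr.ocr_mean[5], tr.ocr_mean[8]
        assert dnp > basal > oligo
        ref = simulate_protocol(
            truth.params, truth.mods("rosi"), catalog["P1"],
            method="Radau", rtol=1e-9, atol=1e-11,
        )
        assert np.allclose(tr.ocr_mean, ref.ocr_mean, rtol=1e-6)

    def test_oligomycin_never_raises_ocr_without_leak(self):
        """With all leak conductances zero, blocking the ATP synthase can only
        lower (never raise) OCR: Δp piles up and throttles the ETC.  (No
        finite steady state exists in this corner, so the property is checked
        on the simulated trajectory.)"""
        p = ModelParameters(L_basal=0.0, L_ucp1=0.0, L_alt=0.0, L_dnp=0.0,
                            a0=0.0, c_dp=0.1)
        m = ConditionModifiers()
        proto = bf.Protocol(
            protocol_id="oligo_only",
            events=[bf.InjectionEvent(10.0, "oligomycin")],
            measurement_times=list(np.arange(0.0, 71.0, 7.0)),
        )
        tr = simulate_protocol(p, m, proto)
        assert np.all(tr.ocr_mean <= tr.ocr_mean[0] + 1e-9)
        assert np.all(np.diff(tr.ocr_mean[2:]) <= 1e-9)  # monotone decay

    def test_steady_state_error_when_no_proton_sink(self):
        p = ModelParameters(L_basal=0.0, L_ucp1=0.0, L_alt=0.0, L_dnp=0.0, a0=0.0)
        with pytest.raises(SteadyStateError):
            steady_state(p, ConditionModifiers(), {"oligomycin"})

    def test_uncoupling_signature_under_oligomycin(self, truth):
        """With the ATP synthase fully blocked, steady mitochondrial OCR
        equals total leak flux."""
        p, m = truth.params, truth.mods("rosi")
        s = steady_state(p, m, {"oligomycin"})
        fx = compute_fluxes(s, p, m)
        assert fx.v_etc == pytest.approx(fx.v_leak, rel=1e-6)

    def test_control_neutrality_to_iso(self, catalog):
        """Without UCP1, an alternative uncoupler, or a substrate drive,
        isoproterenol leaves steady OCR unchanged."""
        p = ModelParameters(s_ffa=0.0)
        tr = simulate_protocol(p, ConditionModifiers(), catalog["P0"])
        assert tr.ocr_mean[-1] == pytest.approx(tr.ocr_mean[0], rel=1e-6)

    def test_steady_ocr_nondecreasing_in_dnp_leak(self):
        ocrs = []
        for L in (0.0, 10.0, 100.0, 1000.0):
            p = ModelParameters(L_dnp=L)
            m = ConditionModifiers()
            s = steady_state(p, m, {"dnp"})
            ocrs.append(compute_fluxes(s, p, m).ocr_total)
        assert all(b >= a - 1e-9 for a, b in zip(ocrs, ocrs[1:]))
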