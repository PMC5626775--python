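"""Fit-for-purpose ODE model of whole-cell oxygen consumption in adipocytes.

The model tracks two dynamic quantities: the proton motive force Δp across the
inner mitochondrial membrane (arbitrary units) and the intracellular free
fatty acid (FFA) level.  Oxygen consumption is read out as the electron
transport chain (ETC) flux plus a non-mitochondrial floor.  The ETC builds Δp
against a hyperbolic back-pressure; Δp is dissipated by the ATP synthase and by
four proton-leak conductances (basal, UCP1-mediated, an FFA-gated alternative
uncoupler, and the chemical uncoupler 2,4-DNP):

    v_etc  = m_mito * k_etc * (1 + s_ffa*ffa) * (1 - e_rot_aa) / (1 + dp/K_dp)
    v_atp  = m_mito * k_atp * dp * (1 - e_oligo)
    A_ucp1 = u_ucp1 * (a0 + a_ffa*ffa + a_ra*e_atra)
    G      = m_mito * (L_basal + L_ucp1*A_ucp1
                       + L_alt*u_alt*ffa^n/(K_alt^n + ffa^n) + L_dnp*e_dnp)
    v_leak = G * dp
    OCR    = v_etc + ocr_nonmito

    c_dp * d(dp)/dt = v_etc - v_atp - v_leak
    d(ffa)/dt = f_ffa*(k_ffa0 + (k_lip*e_iso + k_palm*e_palm)*(1 - e_bsa))
                - k_clr*ffa

Each perturbing agent a (oligomycin, rotenone+antimycin A, DNP, isoproterenol,
all-trans retinoic acid, palmitate-BSA, BSA scavenging, cyclosporine A) has a
first-order onset level e_a in [0, 1] with shared time constant tau_drug;
because the onsets do not feed back on the states they are evaluated in closed
form, e_a(t) = 1 - exp(-(t - t_inj)/tau_drug), and the integrated system is
two-dimensional.  Cyclosporine A (a permeability-transition-pore inhibitor) is
accepted as an agent but has no effect in this model.

Condition-specific "beige" parameters (relative UCP1 protein level,
mitochondrial content, FFA content, alternative-uncoupler level) scale the
shared kinetics per treatment; the control condition is the reference.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint, solve_ivp
from scipy.optimize import brentq

try:  # optional JIT for the right-hand side; pure-Python fallback below
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "AGENTS",
    "ModelParameters",
    "ConditionModifiers",
    "StateVector",
    "FluxVector",
    "compute_fluxes",
    "steady_state",
    "simulate_protocol",
    "SimulationError",
    "SteadyStateError",
]

#: agents that can appear in injection protocols (vehicle is handled at the
#: protocol level and never reaches the model)
AGENTS = (
    "oligomycin",
    "rot_aa",
    "dnp",
    "iso",
    "atra",
    "palmitate_bsa",
    "bsa_scavenge",
    "csa",
)


class SimulationError(RuntimeError):
    """ODE integration failed; carries the failing time."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class SteadyStateError(RuntimeError):
    """Steady-state search did not converge; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


def _check_nonneg(obj, names) -> None:
    for name in names:
        v = getattr(obj, name)
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be >= 0, got {v!r}")


@dataclass
class ModelParameters:
    """Shared kinetic parameters, common to all treatment conditions.

    OCR-scaled parameters are in pmol O2/min per 10^4 cells; Δp and FFA are in
    arbitrary units (only OCR is observed), rates in 1/min.
    """

    k_etc: float = 150.0      # maximal ETC drive (OCR units)
    K_dp: float = 0.5         # Δp back-pressure constant (Δp units)
    k_atp: float = 48.0       # ATP-synthase proton conductance (OCR/Δp)
    L_basal: float = 2.0      # basal proton-leak conductance (OCR/Δp)
    L_ucp1: float = 622.949   # UCP1 leak conductance per unit activity (OCR/Δp)
    L_alt: float = 15.788     # alternative-uncoupler leak conductance (OCR/Δp)
    L_dnp: float = 1000.0     # DNP-induced leak conductance (OCR/Δp)
    a0: float = 0.01          # basal UCP1 activation (dimensionless)
    a_ffa: float = 0.3        # UCP1 activation per unit FFA
    a_ra: float = 2.1         # UCP1 activation by all-trans retinoic acid
    s_ffa: float = 0.005      # substrate-availability drive per unit FFA
    k_ffa0: float = 0.015     # basal FFA appearance rate (FFA/min)
    k_lip: float = 0.9        # Iso-stimulated lipolysis rate (FFA/min)
    k_palm: float = 0.9       # exogenous palmitate supply rate (FFA/min)
    k_clr: float = 0.3        # FFA clearance rate (1/min)
    K_alt: float = 2.0        # half-saturation of the FFA-gated alternative leak
    n_alt: float = 2.0        # Hill exponent of the alternative leak gate
    tau_drug: float = 1.0     # first-order drug onset time constant (min)
    ocr_nonmito: float = 10.0 # non-mitochondrial OCR (OCR units)
    c_dp: float = 10.0        # Δp buffering capacity (Δp·min per OCR unit)

    def __post_init__(self) -> None:
        _check_nonneg(self, [f.name for f in dataclasses.fields(self)])
        if self.n_alt < 1:
            raise ValueError(f"ModelParameters.n_alt must be >= 1, got {self.n_alt}")
        if self.tau_drug <= 0:
            raise ValueError("ModelParameters.tau_drug must be > 0")
        if self.c_dp <= 0:
            raise ValueError("ModelParameters.c_dp must be > 0")

    @classmethod
    def default(cls) -> "ModelParameters":
        return cls()

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kw) -> "ModelParameters":
        return dataclasses.replace(self, **kw)


#: shared parameters exposed as free in the default fit configuration
FREE_SHARED_PARAMETERS = tuple(f.name for f in dataclasses.fields(ModelParameters))


@dataclass
class ConditionModifiers:
    """Per-condition "beige" parameters relative to the control condition."""

    condition_id: str = "control"
    u_ucp1: float = 0.0   # relative UCP1 protein level (control = 0)
    m_mito: float = 1.0   # mitochondrial-content scale (control = 1)
    f_ffa: float = 1.0    # FFA-content scale (control = 1)
    u_alt: float = 0.0    # alternative-uncoupler level (control = 0)

    def __post_init__(self) -> None:
        _check_nonneg(self, ["u_ucp1", "m_mito", "f_ffa", "u_alt"])
        if self.condition_id == "control" and (self.u_ucp1 != 0 or self.u_alt != 0):
            raise ValueError("control condition fixes u_ucp1 = 0 and u_alt = 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kw) -> "ConditionModifiers":
        return dataclasses.replace(self, **kw)


def _zero_agents() -> dict:
    return {a: 0.0 for a in AGENTS}


@dataclass
class StateVector:
    """Instantaneous model state: Δp, FFA and the drug-onset levels."""

    dp: float = 0.0
    ffa: float = 0.0
    e: dict = field(default_factory=_zero_agents)

    def __post_init__(self) -> None:
        if not np.isfinite(self.dp) or self.dp < 0:
            raise ValueError(f"StateVector.dp must be >= 0, got {self.dp!r}")
        if not np.isfinite(self.ffa) or self.ffa < 0:
            raise ValueError(f"StateVector.ffa must be >= 0, got {self.ffa!r}")
        e = dict(_zero_agents())
        for k, v in self.e.items():
            if k not in e:
                raise ValueError(f"unknown agent {k!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"StateVector.e[{k!r}] must be in [0, 1], got {v!r}")
            e[k] = float(v)
        self.e = e


@dataclass
class FluxVector:
    """Flux decomposition at one instant (all in OCR units)."""

    v_etc: float
    v_atp: float
    v_leak_basal: float
    v_leak_ucp1: float
    v_leak_alt: float
    v_leak_dnp: float
    ocr_total: float

    @property
    def v_leak(self) -> float:
        return (
            self.v_leak_basal + self.v_leak_ucp1 + self.v_leak_alt + self.v_leak_dnp
        )


def _fluxes_raw(dp, ffa, e, p: ModelParameters, mods: ConditionModifiers):
    """Scalar flux kernel shared by compute_fluxes and the ODE right-hand side."""
    m = mods.m_mito
    drive = 1.0 + p.s_ffa * ffa
    v_etc = m * p.k_etc * drive * (1.0 - e["rot_aa"]) / (1.0 + dp / p.K_dp)
    v_atp = m * p.k_atp * dp * (1.0 - e["oligomycin"])
    act = mods.u_ucp1 * (p.a0 + p.a_ffa * ffa + p.a_ra * e["atra"])
    if mods.u_alt > 0.0 and ffa > 0.0:
        fn = ffa ** p.n_alt
        hill = fn / (p.K_alt ** p.n_alt + fn)
    else:
        hill = 0.0
    g_basal = m * p.L_basal
    g_ucp1 = m * p.L_ucp1 * act
    g_alt = m * p.L_alt * mods.u_alt * hill
    g_dnp = m * p.L_dnp * e["dnp"]
    return v_etc, v_atp, g_basal * dp, g_ucp1 * dp, g_alt * dp, g_dnp * dp


def compute_fluxes(
    state: StateVector, params: ModelParameters, mods: ConditionModifiers
) -> FluxVector:
    """Evaluate all model fluxes at one state.

    Fluxes are continuous in every input; total OCR is the ETC flux plus the
    non-mitochondrial floor.
    """
    v_etc, v_atp, lb, lu, la, ld = _fluxes_raw(
        state.dp, state.ffa, state.e, params, mods
    )
    return FluxVector(
        v_etc=v_etc,
        v_atp=v_atp,
        v_leak_basal=lb,
        v_leak_ucp1=lu,
        v_leak_alt=la,
        v_leak_dnp=ld,
        ocr_total=v_etc + params.ocr_nonmito,
    )


def _ffa_steady(p: ModelParameters, mods: ConditionModifiers, e: dict) -> float:
    supply = p.k_ffa0 + (p.k_lip * e["iso"] + p.k_palm * e["palmitate_bsa"]) * (
        1.0 - e["bsa_scavenge"]
    )
    if p.k_clr == 0.0:
        if mods.f_ffa * supply > 0.0:
            raise SteadyStateError("FFA has a source but no clearance", residual=supply)
        return 0.0
    return mods.f_ffa * supply / p.k_clr


def _dp_balance(dp, ffa, e, p, mods) -> float:
    v_etc, v_atp, lb, lu, la, ld = _fluxes_raw(dp, ffa, e, p, mods)
    return v_etc - v_atp - (lb + lu + la + ld)


def steady_state(
    params: ModelParameters,
    mods: ConditionModifiers,
    held_agents: set[str] | frozenset[str] = frozenset(),
    rtol: float = 1e-12,
) -> StateVector:
    """Pre-injection baseline: the resting state with ``held_agents`` at full
    onset (e_a = 1) and every other agent absent.

    FFA follows from the supply/clearance balance in closed form; Δp is the
    unique root of the flux balance v_etc - v_atp - v_leak = 0 (the balance is
    strictly decreasing in Δp whenever any conductance is positive).
    """
    for a in held_agents:
        if a not in AGENTS:
            raise ValueError(f"unknown agent {a!r}")
    e = _zero_agents()
    for a in held_agents:
        e[a] = 1.0
    ffa = _ffa_steady(params, mods, e)

    def g(dp):
        return _dp_balance(dp, ffa, e, params, mods)

    g0 = g(0.0)
    if g0 <= 0.0:
        dp = 0.0
    else:
        hi = max(params.K_dp, 1.0)
        for _ in range(200):
            if g(hi) < 0.0:
                break
            hi *= 2.0
        else:
            raise SteadyStateError(
                "no Δp sink: flux balance stays positive", residual=g(hi)
            )
        dp = brentq(g, 0.0, hi, xtol=1e-14, rtol=8.9e-16, maxiter=300)
    state = StateVector(dp=max(dp, 0.0), ffa=ffa, e=e)
    # convergence contract: residual below rtol relative to the flux scale
    scale = max(abs(compute_fluxes(state, params, mods).v_etc), 1.0)
    resid = abs(_dp_balance(state.dp, ffa, e, params, mods)) / scale
    if resid > max(rtol, 1e-9):
        raise SteadyStateError("steady state did not converge", residual=resid)
    return state


def _onset_times(protocol, pre_held) -> dict:
    """First injection time per agent (+inf if never injected)."""
    t_on = {a: math.inf for a in AGENTS}
    for a in pre_held:
        t_on[a] = -math.inf
    for ev in protocol.events:
        if ev.agent == "vehicle":
            continue
        if ev.time_min < t_on[ev.agent]:
            t_on[ev.agent] = ev.time_min
    return t_on


def _onsets_at(t: float, t_on: dict, tau: float) -> dict:
    e = {}
    for a, t0 in t_on.items():
        if t0 == -math.inf:
            e[a] = 1.0
        elif t <= t0:
            e[a] = 0.0
        else:
            e[a] = 1.0 - math.exp(-(t - t0) / tau)
    return e


def _make_rhs(p: ModelParameters, mods: ConditionModifiers, t_on: dict):
    """Fast scalar right-hand side with pre-bound constants.

    Drug onsets are closed-form forcings, so the state is just (Δp, FFA).
    """
    exp = math.exp
    inv_tau = 1.0 / p.tau_drug
    m = mods.m_mito
    ke, ka = m * p.k_etc, m * p.k_atp
    Lb, Lu, La, Ld = m * p.L_basal, m * p.L_ucp1, m * p.L_alt, m * p.L_dnp
    u, ualt, f = mods.u_ucp1, mods.u_alt, mods.f_ffa
    Kdp, s_ffa, a0, a_ffa, a_ra = p.K_dp, p.s_ffa, p.a0, p.a_ffa, p.a_ra
    Kn = p.K_alt ** p.n_alt
    n_alt, c_dp = p.n_alt, p.c_dp
    k_ffa0, k_lip, k_palm, k_clr = p.k_ffa0, p.k_lip, p.k_palm, p.k_clr
    t_rot, t_oli, t_dnp = t_on["rot_aa"], t_on["oligomycin"], t_on["dnp"]
    t_iso, t_ra, t_pal, t_bsa = (
        t_on["iso"], t_on["atra"], t_on["palmitate_bsa"], t_on["bsa_scavenge"],
    )

    if _HAVE_NUMBA:
        c = np.array(
            [
                ke, ka, Lb, Lu * u, La * ualt, Ld, Kdp, s_ffa, a0, a_ffa, a_ra,
                Kn, n_alt, c_dp, f * k_ffa0, f * k_lip, f * k_palm, k_clr,
                inv_tau, t_rot, t_oli, t_dnp, t_iso, t_pal, t_bsa, t_ra,
            ],
            dtype=np.float64,
        )
        return _rhs_nb, (c,)

    neg_inf = -math.inf

    def rhs(y, t):
        dp = y[0] if y[0] > 0.0 else 0.0
        ffa = y[1] if y[1] > 0.0 else 0.0
        e_rot = (1.0 - exp((t_rot - t) * inv_tau)) if t > t_rot else (1.0 if t_rot == neg_inf else 0.0)
        e_oli = (1.0 - exp((t_oli - t) * inv_tau)) if t > t_oli else (1.0 if t_oli == neg_inf else 0.0)
        e_dnp = (1.0 - exp((t_dnp - t) * inv_tau)) if t > t_dnp else (1.0 if t_dnp == neg_inf else 0.0)
        e_iso = (1.0 - exp((t_iso - t) * inv_tau)) if t > t_iso else (1.0 if t_iso == neg_inf else 0.0)
        e_pal = (1.0 - exp((t_pal - t) * inv_tau)) if t > t_pal else (1.0 if t_pal == neg_inf else 0.0)
        e_bsa = (1.0 - exp((t_bsa - t) * inv_tau)) if t > t_bsa else (1.0 if t_bsa == neg_inf else 0.0)
        v_etc = ke * (1.0 + s_ffa * ffa) * (1.0 - e_rot) / (1.0 + dp / Kdp)
        v_atp = ka * dp * (1.0 - e_oli)
        G = Lb + Ld * e_dnp
        if u > 0.0:
            e_ra = (1.0 - exp((t_ra - t) * inv_tau)) if t > t_ra else (1.0 if t_ra == neg_inf else 0.0)
            G += Lu * u * (a0 + a_ffa * ffa + a_ra * e_ra)
        if ualt > 0.0 and ffa > 0.0:
            fn = ffa ** n_alt
            G += La * ualt * fn / (Kn + fn)
        supply = k_ffa0 + (k_lip * e_iso + k_palm * e_pal) * (1.0 - e_bsa)
        return ((v_etc - v_atp - G * dp) / c_dp, f * supply - k_clr * ffa)

    return rhs, ()


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _rhs_nb(y, t, c):  # pragma: no cover - exercised through simulate
        dp = y[0] if y[0] > 0.0 else 0.0
        ffa = y[1] if y[1] > 0.0 else 0.0
        inv_tau = c[18]
        e_rot = 1.0 - math.exp((c[19] - t) * inv_tau) if t > c[19] else 0.0
        e_oli = 1.0 - math.exp((c[20] - t) * inv_tau) if t > c[20] else 0.0
        e_dnp = 1.0 - math.exp((c[21] - t) * inv_tau) if t > c[21] else 0.0
        e_iso = 1.0 - math.exp((c[22] - t) * inv_tau) if t > c[22] else 0.0
        e_pal = 1.0 - math.exp((c[23] - t) * inv_tau) if t > c[23] else 0.0
        e_bsa = 1.0 - math.exp((c[24] - t) * inv_tau) if t > c[24] else 0.0
        e_ra = 1.0 - math.exp((c[25] - t) * inv_tau) if t > c[25] else 0.0
        v_etc = c[0] * (1.0 + c[7] * ffa) * (1.0 - e_rot) / (1.0 + dp / c[6])
        v_atp = c[1] * dp * (1.0 - e_oli)
        G = c[2] + c[5] * e_dnp
        if c[3] > 0.0:
            G += c[3] * (c[8] + c[9] * ffa + c[10] * e_ra)
        if c[4] > 0.0 and ffa > 0.0:
            fn = ffa ** c[12]
            G += c[4] * fn / (c[11] + fn)
        supply = c[14] + (c[15] * e_iso + c[16] * e_pal) * (1.0 - e_bsa)
        out = np.empty(2)
        out[0] = (v_etc - v_atp - G * dp) / c[13]
        out[1] = supply - c[17] * ffa
        return out


def simulate_protocol(
    params: ModelParameters,
    mods: ConditionModifiers,
    protocol,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
):
    """Deterministic, noiseless simulation of one injection protocol.

    The initial state is the steady state with the protocol's pre-held agents;
    the stiff-capable default integrator (LSODA) is told about the injection
    times (derivative kinks) and the trace is sampled at the protocol's
    measurement times.  Any other ``method`` accepted by
    :func:`scipy.integrate.solve_ivp` (e.g. ``"Radau"``) integrates piecewise
    between injections instead.  Returns an :class:`~beigeflux.io.OCRTrace`
    with zero SEM and ``n_wells = 0``.
    """
    from .io import OCRTrace  # local import to avoid a cycle

    protocol.validate()
    pre_held = frozenset(protocol.pre_held_agents)
    t_on = _onset_times(protocol, pre_held)
    times = np.asarray(protocol.measurement_times, dtype=float)
    state0 = steady_state(params, mods, pre_held)
    p = params
    rhs_fast, rhs_args = _make_rhs(p, mods, t_on)

    if method == "LSODA":
        tcrit = np.array(
            [t for t in t_on.values() if math.isfinite(t) and times[0] < t < times[-1]]
        )
        import warnings

        with warnings.catch_warnings():
            # failures are detected via the info dict and raised as
            # SimulationError; the lsoda warning text is redundant noise
            warnings.simplefilter("ignore")
            y, info = odeint(
                rhs_fast,
                [state0.dp, state0.ffa],
                times,
                args=rhs_args,
                rtol=rtol,
                atol=atol,
                tcrit=np.sort(tcrit) if len(tcrit) else None,
                mxstep=100000,
                full_output=True,
            )
        if info["message"] != "Integration successful.":
            raise SimulationError(
                f"ODE integration failed: {info['message']}",
                time=float(info["tcur"][-1]) if len(info.get("tcur", [])) else None,
            )
        ocr = np.empty_like(times)
        for i, (tk, yk) in enumerate(zip(times, y)):
            e = _onsets_at(tk, t_on, p.tau_drug)
            ocr[i] = (
                _fluxes_raw(max(yk[0], 0.0), max(yk[1], 0.0), e, p, mods)[0]
                + p.ocr_nonmito
            )
        return OCRTrace(
            experiment_id=f"sim:{protocol.protocol_id}:{mods.condition_id}",
            condition_id=mods.condition_id,
            protocol_id=protocol.protocol_id,
            time_min=times,
            ocr_mean=ocr,
            ocr_sem=np.zeros_like(times),
            n_wells=0,
        )

    def rhs(t, y):
        return rhs_fast(y, t, *rhs_args)

    t_start = float(times[0])
    t_end = float(times[-1])
    breaks = sorted(
        {t_start, t_end}
        | {t for t in t_on.values() if t_start < t < t_end and math.isfinite(t)}
    )
    y = np.array([state0.dp, state0.ffa], dtype=float)
    ocr = np.empty_like(times)
    # the first measurement is the pre-injection baseline by construction
    mask0 = times <= t_start
    e0 = _onsets_at(t_start, t_on, p.tau_drug)
    ocr[mask0] = (
        _fluxes_raw(y[0], y[1], e0, p, mods)[0] + p.ocr_nonmito
    )
    for a, b in zip(breaks[:-1], breaks[1:]):
        t_eval = [t for t in times if a < t <= b]
        if not t_eval or t_eval[-1] < b:
            t_eval.append(b)  # always evaluate the endpoint to continue from it
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            dense_output=False,
        )
        if not sol.success:
            raise SimulationError(
                f"ODE integration failed in [{a}, {b}]: {sol.message}", time=b
            )
        for tk, yk in zip(sol.t, sol.y.T):
            idx = int(np.searchsorted(times, tk))
            if idx < len(times) and times[idx] == tk:
                e = _onsets_at(tk, t_on, p.tau_drug)
                ocr[idx] = (
                    _fluxes_raw(max(yk[0], 0.0), max(yk[1], 0.0), e, p, mods)[0]
                    + p.ocr_nonmito
                )
        y = sol.y[:, -1]
    return OCRTrace(
        experiment_id=f"sim:{protocol.protocol_id}:{mods.condition_id}",
        condition_id=mods.condition_id,
        protocol_id=protocol.protocol_id,
        time_min=times,
        ocr_mean=ocr,
        ocr_sem=np.zeros_like(times),
        n_wells=0,
    )
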