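"""The three uncoupling hypotheses and the iterative rejection workflow.

BMP4-treated beige adipocytes respire and uncouple like thermogenic cells yet
show no detectable UCP1 protein.  Three scenarios can explain their increased
oxygen consumption upon isoproterenol:

* **H1** — no uncoupler at all: neither UCP1 nor any alternative mechanism;
  the Iso response would have to come from substrate availability alone.
* **H2** — a trace amount of UCP1 (below the immunoblot detection limit) with
  a non-linear protein→flux relation, i.e. high specific activity.
* **H3** — an alternative, UCP1-independent uncoupling mechanism.

All hypotheses keep control cells free of uncouplers and attribute Rosi-driven
uncoupling to UCP1.  The workflow fits each hypothesis to the dynamic OCR data
(stage A), then adds the direct-UCP1-activation experiment (all-trans retinoic
acid in BMP4 cells, stage B) and refits the survivors.  Rejection is monotone:
a hypothesis rejected at stage A stays rejected.  Prediction-band overlap on
the stage-B design quantifies whether that experiment can discriminate the
surviving hypotheses, and a held-out reversed-order protocol validates the
final model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .estimation import (
    Dataset,
    FitResult,
    ParameterEnsemble,
    PredictionBand,
    collect_ensemble,
    fit_hypothesis,
    prediction_band,
)
from .io import OCRTrace

__all__ = [
    "Hypothesis",
    "HypothesisReport",
    "build_hypothesis",
    "run_hypothesis_test",
    "band_overlap",
    "validate_prediction",
    "HYPOTHESIS_IDS",
]

HYPOTHESIS_IDS = ("H1", "H2", "H3")


@dataclass
class Hypothesis:
    """Per-condition constraints on the beige modifiers.

    Constraint forms: ``("fix", value)``, ``("free",)`` (default bounds) or
    ``("free", lo, hi)``, and ``("detect", frac)`` for the H2 coupling
    u_ucp1(bmp4) ≤ frac · u_ucp1(rosi).
    """

    hypothesis_id: str
    constraints: dict
    description: str = ""


def build_hypothesis(hypothesis_id: str, config: RunConfig | None = None) -> Hypothesis:
    """Construct H1, H2 or H3 with the standard condition constraints."""
    config = config or RunConfig()
    if hypothesis_id not in HYPOTHESIS_IDS:
        raise ValueError(
            f"unknown hypothesis {hypothesis_id!r}; expected one of {HYPOTHESIS_IDS}"
        )
    base = {
        "control": {
            "u_ucp1": ("fix", 0.0),
            "m_mito": ("fix", 1.0),
            "f_ffa": ("fix", 1.0),
            "u_alt": ("fix", 0.0),
        },
        "rosi": {
            "u_ucp1": ("free",) + (1e-2, 1e2),
            "m_mito": ("free",) + (0.2, 5.0),
            "f_ffa": ("free",) + (0.5, 3.0),
            "u_alt": ("fix", 0.0),
        },
        "bmp4": {
            "m_mito": ("free",) + (0.2, 5.0),
            "f_ffa": ("free",) + (0.5, 3.0),
        },
    }
    if hypothesis_id == "H1":
        base["bmp4"]["u_ucp1"] = ("fix", 0.0)
        base["bmp4"]["u_alt"] = ("fix", 0.0)
        desc = "no uncoupling in BMP4 cells (substrate availability only)"
    elif hypothesis_id == "H2":
        base["bmp4"]["u_ucp1"] = ("detect", config.delta_detect_frac)
        base["bmp4"]["u_alt"] = ("fix", 0.0)
        desc = "sub-detection UCP1 with high specific activity in BMP4 cells"
    else:
        base["bmp4"]["u_ucp1"] = ("fix", 0.0)
        base["bmp4"]["u_alt"] = ("free",) + (1e-2, 1e2)
        desc = "UCP1-independent alternative uncoupler in BMP4 cells"
    return Hypothesis(hypothesis_id=hypothesis_id, constraints=base, description=desc)


# ---------------------------------------------------------------------------
# band comparison and validation

def band_overlap(
    band_a: PredictionBand,
    band_b: PredictionBand,
    data_sem,
    cutoff: float = 0.0,
    eval_from_time: float | None = None,
):
    """Pointwise overlap of two prediction bands, each widened by one SEM.

    Returns ``(overlap_fraction, discriminable)``.  ``overlap_fraction`` is
    the fraction of time points where the widened intervals intersect.  With
    the default cutoff of 0 the designs are called discriminable when the
    bands are disjoint somewhere in the evaluation window (time ≥
    ``eval_from_time``, default: everywhere); a positive cutoff instead
    requires the windowed overlap fraction to fall at or below it.
    """
    if len(band_a.times) != len(band_b.times) or not np.allclose(
        band_a.times, band_b.times
    ):
        raise ValueError("prediction bands are not on the same time grid")
    sem = np.broadcast_to(np.asarray(data_sem, dtype=float), band_a.times.shape)
    lo_a, hi_a = band_a.lower - sem, band_a.upper + sem
    lo_b, hi_b = band_b.lower - sem, band_b.upper + sem
    overlap = (lo_a <= hi_b) & (lo_b <= hi_a)
    overlap_fraction = float(np.mean(overlap))
    window = (
        np.ones_like(overlap, dtype=bool)
        if eval_from_time is None
        else band_a.times >= eval_from_time
    )
    if cutoff <= 0.0:
        discriminable = bool(np.any(~overlap & window))
    else:
        discriminable = float(np.mean(overlap[window])) <= cutoff
    return overlap_fraction, discriminable


def validate_prediction(
    band: PredictionBand,
    new_data: OCRTrace,
    k_sem: float = 1.0,
    coverage_cutoff: float = 0.9,
):
    """Coverage of held-out data by a prediction band (± k_sem · SEM).

    Returns ``(coverage, passed)`` where coverage is the fraction of data
    means inside ``[lower − k_sem·SEM, upper + k_sem·SEM]``.
    """
    if len(band.times) != len(new_data.time_min) or not np.allclose(
        band.times, new_data.time_min
    ):
        raise ValueError("validation data are not on the band's time grid")
    slack = k_sem * new_data.ocr_sem
    inside = (new_data.ocr_mean >= band.lower - slack) & (
        new_data.ocr_mean <= band.upper + slack
    )
    coverage = float(np.mean(inside))
    return coverage, coverage >= coverage_cutoff


# ---------------------------------------------------------------------------
# staged workflow

@dataclass
class HypothesisReport:
    """Outcome of the iterative hypothesis test.

    ``status[h][stage]`` is "rejected" or "retained"; rejection is monotone
    across stages.  Stage-B fits exist only for stage-A survivors.
    """

    stage_a: dict = field(default_factory=dict)   # hyp id -> FitResult
    stage_b: dict = field(default_factory=dict)   # hyp id -> FitResult
    status: dict = field(default_factory=dict)    # hyp id -> {stage: verdict}
    discrimination: dict | None = None
    validation: dict | None = None
    ensembles: dict = field(default_factory=dict) # (hyp id, stage) -> ensemble
    config: RunConfig | None = None

    def retained(self, stage: str = "stage_b") -> list[str]:
        return [h for h, s in sorted(self.status.items()) if s.get(stage) == "retained"]

    def check_monotone(self) -> None:
        for h, s in self.status.items():
            if s.get("stage_a") == "rejected" and s.get("stage_b") == "retained":
                raise AssertionError(f"{h}: rejection is not monotone across stages")

    def to_dict(self) -> dict:
        d = {
            "status": self.status,
            "stage_a": {h: f.to_dict() for h, f in self.stage_a.items()},
            "stage_b": {h: f.to_dict() for h, f in self.stage_b.items()},
            "discrimination": self.discrimination,
            "validation": self.validation,
            "ensembles": {
                f"{h}:{stage}": e.to_dict() for (h, stage), e in self.ensembles.items()
            },
        }
        if self.config is not None:
            d["config"] = self.config.to_dict()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def summary(self) -> str:
        lines = ["hypothesis  stage A     stage B"]
        for h in sorted(self.status):
            s = self.status[h]
            lines.append(
                f"{h:<11} {s.get('stage_a', '-'):<11} {s.get('stage_b', '-')}"
            )
        if self.discrimination is not None:
            lines.append(
                "discriminating experiment "
                f"({self.discrimination['protocol_id']}/"
                f"{self.discrimination['condition_id']}): "
                f"overlap {self.discrimination['overlap_fraction']:.2f}, "
                f"discriminable={self.discrimination['discriminable']}"
            )
        if self.validation is not None:
            lines.append(
                f"validation ({self.validation['protocol_id']}): coverage "
                f"{self.validation['coverage']:.2f}, passed={self.validation['passed']}"
            )
        return "\n".join(lines)


def run_hypothesis_test(
    stage_a: Dataset,
    stage_b_extra: Dataset,
    config: RunConfig | None = None,
    *,
    hypothesis_ids=HYPOTHESIS_IDS,
    compute_discrimination: bool = True,
    discrimination_experiment: tuple[str, str] = ("P3", "bmp4"),
    validation_data: tuple | None = None,
) -> HypothesisReport:
    """Fit all hypotheses on stage A, refit stage-A survivors on A ∪ B.

    ``validation_data``, when given, is a ``(protocol, OCRTrace)`` pair held
    out from fitting; the final retained hypothesis's combined-fit ensemble is
    simulated under that protocol and checked for coverage of the data.
    """
    config = config or RunConfig()
    report = HypothesisReport(config=config)
    combined = stage_a.merged(stage_b_extra)
    hyps = {h: build_hypothesis(h, config) for h in hypothesis_ids}

    for h, hyp in hyps.items():
        fit = fit_hypothesis(stage_a, hyp, config)
        report.stage_a[h] = fit
        report.status[h] = {
            "stage_a": "rejected" if fit.rejected else "retained"
        }

    for h, hyp in hyps.items():
        if report.status[h]["stage_a"] == "rejected":
            report.status[h]["stage_b"] = "rejected"  # monotone by construction
            continue
        warm = config.replace(seed=config.seed + 1)
        fit_b = _refit_warm(combined, hyp, report.stage_a[h], warm)
        report.stage_b[h] = fit_b
        report.status[h]["stage_b"] = "rejected" if fit_b.rejected else "retained"

    if compute_discrimination:
        pid, cond = discrimination_experiment
        protocol = _find_protocol(combined, pid)
        cand = [
            h
            for h in ("H2", "H3")
            if h in report.stage_a and not report.stage_a[h].rejected
        ]
        if protocol is not None and len(cand) == 2:
            bands = {}
            for h in cand:
                ens = collect_ensemble(stage_a, hyps[h], report.stage_a[h], config)
                report.ensembles[(h, "stage_a")] = ens
                bands[h] = prediction_band(ens, cond, protocol, config)
            sem = _data_sem_for(combined, pid, cond, config)
            inj = protocol.injection_times
            frac, disc = band_overlap(
                bands[cand[0]],
                bands[cand[1]],
                sem,
                cutoff=config.discriminability_cutoff,
                eval_from_time=inj[-1] if inj else None,
            )
            report.discrimination = {
                "protocol_id": pid,
                "condition_id": cond,
                "hypotheses": cand,
                "overlap_fraction": frac,
                "discriminable": disc,
            }

    if validation_data is not None:
        protocol, trace = validation_data
        final = [h for h in report.retained("stage_b")]
        if final:
            h = final[-1]
            ens = collect_ensemble(combined, hyps[h], report.stage_b[h], config)
            report.ensembles[(h, "stage_b")] = ens
            band = prediction_band(ens, trace.condition_id, protocol, config)
            coverage, passed = validate_prediction(
                band,
                trace,
                k_sem=config.validation_k_sem,
                coverage_cutoff=config.validation_coverage_cutoff,
            )
            report.validation = {
                "protocol_id": protocol.protocol_id,
                "hypothesis_id": h,
                "coverage": coverage,
                "passed": passed,
            }

    report.check_monotone()
    return report


def _refit_warm(dataset, hyp, fit_a: FitResult, config: RunConfig) -> FitResult:
    """Stage-B refit warm-started from the stage-A optimum (plus fresh starts)."""
    fit = fit_hypothesis(dataset, hyp, config)
    if fit_a.x_best is not None and fit.space.dim == len(fit_a.x_best):
        from .estimation import _residual_builder
        from scipy.optimize import least_squares

        residuals = _residual_builder(dataset, fit.space, config)
        lo, hi = fit.space.bounds
        sol = least_squares(
            residuals,
            np.clip(fit_a.x_best, lo, hi),
            bounds=(lo, hi),
            method="trf",
            ftol=config.ftol,
            xtol=1e-10,
            diff_step=config.diff_step,
            max_nfev=config.max_nfev,
        )
        cost = float(2.0 * sol.cost)
        if cost < fit.best_cost:
            params, mods = fit.space.decode(sol.x)
            fit.best_params, fit.best_mods = params, mods
            fit.best_cost = cost
            fit.rejected = cost > fit.threshold
            fit.x_best = sol.x
            fit.meta["warm_start_used"] = True
    return fit


def _find_protocol(dataset: Dataset, protocol_id: str):
    for e in dataset.experiments.values():
        if e.protocol.protocol_id == protocol_id:
            return e.protocol
    from .protocols import build_standard_protocols

    return build_standard_protocols().get(protocol_id)


def _data_sem_for(dataset: Dataset, protocol_id: str, condition_id: str, config):
    for e in dataset.experiments.values():
        if e.protocol.protocol_id == protocol_id and e.condition_id == condition_id:
            return np.maximum(e.trace.ocr_sem, config.sem_floor)
    return config.sem_floor
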