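"""Synthetic Seahorse-like OCR study with known ground truth.

The generator emulates the reference study's design: control white adipocytes,
rosiglitazone-induced beige adipocytes (UCP1-positive) and BMP4-induced beige
adipocytes (no detectable UCP1), each measured under the standard protocol
catalog.  The shipped default truth is an H3 world — BMP4 uncoupling is carried
by an FFA-gated alternative uncoupler, not UCP1 — calibrated so that noiseless
simulation reproduces the study's headline effect pattern:

(a) isoproterenol doubles total OCR in Rosi cells (2.0 ± 10 %);
(b) isoproterenol leaves control cells essentially unchanged (≤ 5 %);
(c) the Rosi all-trans-RA response is the same order of magnitude as its Iso
    response (within 3×);
(d) BMP4 cells do not respond to all-trans RA (≤ 5 % of their Iso response);
(e) BSA scavenging of extracellular FFA abolishes the BMP4 Iso response;
(f) exogenous palmitate-BSA mimics the BMP4 Iso response (within 2×).

Noise: independent Gaussian error per simulated well with
sd = max(sd_abs, sd_rel·|OCR|); reported traces carry the well mean and SEM.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .estimation import Dataset, Experiment
from .io import OCRTrace
from .model import ConditionModifiers, ModelParameters, simulate_protocol
from .protocols import Protocol, build_standard_protocols

__all__ = [
    "TruthPreset",
    "NoiseModel",
    "default_truth",
    "generate_trace",
    "generate_study",
    "split_stages",
    "STUDY_DESIGN",
]

#: (protocol_id, condition_id) pairs making up the reference study
STUDY_DESIGN = (
    ("P1", "control"),
    ("P1", "rosi"),
    ("P2", "control"),
    ("P2", "rosi"),
    ("P2", "bmp4"),
    ("P2v", "control"),
    ("P2v", "rosi"),
    ("P2v", "bmp4"),
    ("P3", "rosi"),
    ("P3", "bmp4"),
    ("P4", "bmp4"),
    ("P5", "rosi"),
    ("P5", "bmp4"),
    ("P6", "bmp4"),
    ("P7", "bmp4"),
)

#: experiments fitted in stage A of the hypothesis workflow: all dynamic OCR
#: data from control and Rosi cells plus the BMP4 oligomycin/Iso experiments
STAGE_A = (
    ("P1", "control"),
    ("P1", "rosi"),
    ("P2", "control"),
    ("P2", "rosi"),
    ("P2", "bmp4"),
    ("P2v", "control"),
    ("P2v", "rosi"),
    ("P2v", "bmp4"),
    ("P3", "rosi"),
)
#: stage-B extra data: direct UCP1 activation in BMP4 cells
STAGE_B_EXTRA = (("P3", "bmp4"),)
#: held out of all fitting; used only for final-model validation
VALIDATION = (("P4", "bmp4"),)


@dataclass
class TruthPreset:
    """Ground-truth parameters for one simulated world."""

    params: ModelParameters
    modifiers: dict
    truth_hypothesis_id: str = "H3"
    preset_id: str = "default"
    notes: str = ""

    def mods(self, condition_id: str) -> ConditionModifiers:
        return self.modifiers[condition_id]


@dataclass
class NoiseModel:
    """Per-well Gaussian measurement noise."""

    sd_rel: float = 0.05
    sd_abs: float = 0.5
    n_wells: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.sd_rel < 0 or self.sd_abs < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.n_wells < 2:
            raise ValueError("n_wells must be >= 2")


# Calibrated truth constants: L_ucp1 tuned once so the Rosi P0 post-Iso/basal
# phase-mean ratio is 2.00; L_alt so the BMP4 P2 post-Iso/post-oligomycin
# ratio is 2.0; the H2 counterfactual u_ucp1 so the H2 and H3 worlds produce
# the same BMP4 Iso response on stage-A data.
_ROSI_MODS = dict(u_ucp1=1.0, m_mito=1.5, f_ffa=1.5, u_alt=0.0)
_BMP4_H3 = dict(u_ucp1=0.0, m_mito=1.3, f_ffa=2.0, u_alt=1.0)
_BMP4_H1 = dict(u_ucp1=0.0, m_mito=1.3, f_ffa=2.0, u_alt=0.0)
_BMP4_H2 = dict(u_ucp1=0.01432, m_mito=1.3, f_ffa=2.0, u_alt=0.0)
_TRUTH_L_UCP1 = 622.949
_TRUTH_L_ALT = 15.788


def default_truth(truth_hypothesis_id: str = "H3") -> TruthPreset:
    """The shipped calibrated truth preset for an H1, H2 or H3 world.

    H3 is the reference study's truth; H1 and H2 are counterfactual worlds for
    testing the discrimination machinery (the H2 world is constructed to be
    indistinguishable from H3 on stage-A data).
    """
    if truth_hypothesis_id not in ("H1", "H2", "H3"):
        raise ValueError(f"unknown hypothesis id {truth_hypothesis_id!r}")
    params = ModelParameters()  # package defaults are the calibrated truth
    bmp4 = {"H1": _BMP4_H1, "H2": _BMP4_H2, "H3": _BMP4_H3}[truth_hypothesis_id]
    modifiers = {
        "control": ConditionModifiers(condition_id="control"),
        "rosi": ConditionModifiers(condition_id="rosi", **_ROSI_MODS),
        "bmp4": ConditionModifiers(condition_id="bmp4", **bmp4),
    }
    return TruthPreset(
        params=params,
        modifiers=modifiers,
        truth_hypothesis_id=truth_hypothesis_id,
        preset_id=f"default-{truth_hypothesis_id}",
        notes="calibrated to the study's qualitative effect pattern",
    )


def generate_trace(
    preset: TruthPreset,
    condition_id: str,
    protocol: Protocol,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> OCRTrace:
    """One noisy mean ± SEM trace for (condition, protocol) under the preset.

    Per-well traces are the noiseless simulation plus independent Gaussian
    noise; the reported mean is the well mean and the SEM the well standard
    deviation over √n_wells.  Deterministic given the noise seed.
    """
    noise = noise or NoiseModel()
    sim = simulate_protocol(preset.params, preset.mods(condition_id), protocol)
    if noise.sd_rel == 0 and noise.sd_abs == 0:
        return dataclasses.replace(
            sim, experiment_id=f"{protocol.protocol_id}:{condition_id}"
        )
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    sd = np.maximum(noise.sd_abs, noise.sd_rel * np.abs(sim.ocr_mean))
    wells = sim.ocr_mean + rng.normal(0.0, 1.0, size=(noise.n_wells, len(sim))) * sd
    return OCRTrace(
        experiment_id=f"{protocol.protocol_id}:{condition_id}",
        condition_id=condition_id,
        protocol_id=protocol.protocol_id,
        time_min=sim.time_min,
        ocr_mean=wells.mean(axis=0),
        ocr_sem=wells.std(axis=0, ddof=1) / np.sqrt(noise.n_wells),
        n_wells=noise.n_wells,
    )


def generate_study(
    preset: TruthPreset | None = None, noise: NoiseModel | None = None
) -> Dataset:
    """The full synthetic reference study as a fit-ready :class:`Dataset`.

    Emits every (protocol, condition) pair of the study design exactly once;
    provenance records the preset id and seed.
    """
    preset = preset or default_truth()
    noise = noise or NoiseModel()
    catalog = build_standard_protocols()
    # one child seed per experiment, in fixed design order
    children = np.random.SeedSequence(noise.seed).spawn(len(STUDY_DESIGN))
    ds = Dataset(
        provenance={
            "kind": "synthetic",
            "preset": preset.preset_id,
            "truth_hypothesis_id": preset.truth_hypothesis_id,
            "seed": noise.seed,
            "noise": dataclasses.asdict(noise),
        }
    )
    for (pid, cond), ss in zip(STUDY_DESIGN, children):
        trace = generate_trace(
            preset, cond, catalog[pid], noise, rng=np.random.default_rng(ss)
        )
        ds.add(Experiment(trace=trace, protocol=catalog[pid], condition_id=cond))
    return ds


def split_stages(dataset: Dataset):
    """Split a study into (stage A, stage B extra, validation) datasets."""

    def pick(design):
        ids = [f"{pid}:{cond}" for pid, cond in design]
        return dataset.subset([i for i in ids if i in dataset.experiments])

    return pick(STAGE_A), pick(STAGE_B_EXTRA), pick(VALIDATION)


def write_manifest(dataset: Dataset, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "provenance": dataset.provenance,
                "experiments": sorted(dataset.experiments),
            },
            fh,
            indent=1,
        )
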