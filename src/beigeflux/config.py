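"""Run configuration shared by fitting, ensemble collection and reporting.

Every output artifact embeds the configuration and seed that produced it, so a
run can be reproduced from its files alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass


@dataclass
class RunConfig:
    # chi-square rejection
    alpha: float = 0.05                 # significance level of the χ² bound
    # optimizer budget
    n_starts: int = 3                   # multi-start count (first start = defaults)
    max_nfev: int = 2500                # residual evaluations per start
    start_spread_decades: float = 1.0   # LHS sampling half-width around defaults (log10)
    ftol: float = 1e-6                  # relative cost tolerance of the optimizer
    diff_step: float = 1e-4             # finite-difference step in log10 space
    # uncertainty machinery
    ensemble_min_members: int = 20
    ensemble_n_proposals: int = 600
    ensemble_steps: tuple = (0.03, 0.1, 0.3)  # proposal σ in log10 units, cycled
    # data weighting: fitted uncertainties are max(SEM, sem_floor,
    # sem_floor_rel*|OCR|).  SEMs estimated from a handful of wells are noisy
    # and heavy-tailed; the relative floor encodes the minimum plate-assay
    # technical variability and keeps the χ² calibration honest.
    sem_floor: float = 0.5              # OCR units
    sem_floor_rel: float = 0.022        # fraction of the measured value
    # hypothesis workflow
    delta_detect_frac: float = 0.1      # H2 UCP1 bound as a fraction of Rosi's level
    discriminability_cutoff: float = 0.0
    validation_coverage_cutoff: float = 0.9
    validation_k_sem: float = 1.0
    freeze_shared_at_stage_b: bool = False
    # integration tolerances used inside fitting loops; looser than the
    # simulation default because residuals are noise-dominated (SEM >= 0.5)
    rtol: float = 1e-6
    atol: float = 1e-8
    # randomness
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_starts < 1 or self.max_nfev < 1:
            raise ValueError("optimizer budget must be positive")
        if self.ensemble_min_members < 0 or self.ensemble_n_proposals < 0:
            raise ValueError("ensemble sizes must be >= 0")
        if self.sem_floor < 0:
            raise ValueError("sem_floor must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ensemble_steps"] = list(d["ensemble_steps"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "ensemble_steps" in d:
            d["ensemble_steps"] = tuple(d["ensemble_steps"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def digest(self) -> str:
        """Short stable hash of the configuration, for provenance logging."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)
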