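"""Trace container and on-disk formats.

The universal data object is :class:`OCRTrace`: a timestamped oxygen-consumption
series (mean, SEM, replicate count) for one condition under one injection
protocol.  Measured data, noiseless simulations and synthetic datasets all use
the same container.  Traces are stored as plain CSV with a fixed header so that
files round-trip losslessly through pandas.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("beigeflux")

#: exact CSV header, in order
TRACE_COLUMNS = [
    "experiment_id",
    "condition_id",
    "protocol_id",
    "time_min",
    "ocr_mean",
    "ocr_sem",
    "n_wells",
]


class ValidationError(ValueError):
    """Raised when an input file or container violates its schema."""


@dataclass
class OCRTrace:
    """Oxygen consumption rate time series for one experiment.

    OCR is in pmol O2/min normalized to 10^4 cells; time in minutes from the
    first measurement.  ``n_wells`` is 0 for noiseless simulations.
    """

    experiment_id: str
    condition_id: str
    protocol_id: str
    time_min: np.ndarray
    ocr_mean: np.ndarray
    ocr_sem: np.ndarray
    n_wells: int = 0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.ocr_mean = np.asarray(self.ocr_mean, dtype=float)
        self.ocr_sem = np.asarray(self.ocr_sem, dtype=float)
        n = len(self.time_min)
        if len(self.ocr_mean) != n or len(self.ocr_sem) != n:
            raise ValidationError(
                f"{self.experiment_id}: time/mean/sem columns have unequal lengths"
            )
        if n and np.any(np.diff(self.time_min) <= 0):
            raise ValidationError(
                f"{self.experiment_id}: time_min must be strictly increasing"
            )
        if np.any(self.ocr_sem < 0):
            raise ValidationError(f"{self.experiment_id}: negative ocr_sem")
        if self.n_wells < 0:
            raise ValidationError(f"{self.experiment_id}: negative n_wells")

    def __len__(self) -> int:
        return len(self.time_min)

    def with_values(self, mean=None, sem=None) -> "OCRTrace":
        """Copy of the trace with replaced mean and/or SEM columns."""
        return dataclasses.replace(
            self,
            ocr_mean=self.ocr_mean if mean is None else np.asarray(mean, float),
            ocr_sem=self.ocr_sem if sem is None else np.asarray(sem, float),
        )


def traces_to_frame(traces: list[OCRTrace]) -> pd.DataFrame:
    rows = []
    for t in traces:
        rows.append(
            pd.DataFrame(
                {
                    "experiment_id": t.experiment_id,
                    "condition_id": t.condition_id,
                    "protocol_id": t.protocol_id,
                    "time_min": t.time_min,
                    "ocr_mean": t.ocr_mean,
                    "ocr_sem": t.ocr_sem,
                    "n_wells": t.n_wells,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(rows, ignore_index=True)[TRACE_COLUMNS]


def write_traces(traces: list[OCRTrace], path) -> None:
    """Write traces as CSV (UTF-8, '.' decimal, 12+ significant digits)."""
    df = traces_to_frame(traces)
    df.to_csv(path, index=False, float_format="%.12g")


def read_traces(path) -> list[OCRTrace]:
    """Read traces from CSV, validating the schema.

    Rows within an experiment may arrive in any order; they are sorted by time
    (with a warning) before validation.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    traces = []
    for exp_id, g in df.groupby("experiment_id", sort=False):
        if not g["time_min"].is_monotonic_increasing:
            logger.warning("experiment %s: rows out of time order; sorting", exp_id)
            g = g.sort_values("time_min")
        cond = g["condition_id"].iloc[0]
        prot = g["protocol_id"].iloc[0]
        if (g["condition_id"] != cond).any() or (g["protocol_id"] != prot).any():
            raise ValidationError(
                f"{path}: experiment {exp_id} mixes conditions or protocols"
            )
        if (g["ocr_sem"] < 0).any():
            row = int(g.index[g["ocr_sem"] < 0][0])
            raise ValidationError(f"{path}: negative ocr_sem at row {row}")
        traces.append(
            OCRTrace(
                experiment_id=str(exp_id),
                condition_id=str(cond),
                protocol_id=str(prot),
                time_min=g["time_min"].to_numpy(),
                ocr_mean=g["ocr_mean"].to_numpy(),
                ocr_sem=g["ocr_sem"].to_numpy(),
                n_wells=int(g["n_wells"].iloc[0]),
            )
        )
    return traces
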