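"""Generate the synthetic reference study and inspect one trace.

The generator simulates every (protocol, condition) pair of the study design
under the calibrated H3 ground truth, adds per-well Gaussian noise, and
reports mean ± SEM — the same shape as a plate-reader export.  The isoproterenol
fold change in the Rosi arm is the study's headline calibration anchor.
"""

import numpy as np

import beigeflux as bf
from beigeflux.synth import NoiseModel

study = bf.generate_study(bf.default_truth("H3"), NoiseModel(seed=1))
print(f"{len(study)} experiments, {study.n_points} time points total")
print("provenance:", study.provenance["preset"], "seed", study.provenance["seed"])

trace = study.experiments["P2:bmp4"].trace
print("\nBMP4 cells, oligomycin -> isoproterenol (P2):")
for t, m, s in zip(trace.time_min, trace.ocr_mean, trace.ocr_sem):
    print(f"  t={t:5.0f} min  OCR = {m:6.1f} ± {s:4.1f}")

pre = trace.ocr_mean[4:6].mean()   # post-oligomycin phase (first point dropped)
post = trace.ocr_mean[7:].mean()   # post-Iso phase
print(f"\nuncoupled OCR rises ~{post / pre:.1f}-fold after Iso "
      "despite these cells having no detectable UCP1 protein.")

bf.write_traces([e.trace for e in study.experiments.values()], "study.csv")
print("wrote study.csv")
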