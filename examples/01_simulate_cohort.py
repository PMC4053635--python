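"""Generate a case-control thrombolysis cohort and inspect its contrasts.

Draws 16 SICH cases and 100 non-SICH controls from the generative risk
model (logistic in NIHSS, ischemia extent and background burden) and prints
the group means that the model is calibrated to reproduce.
"""

import numpy as np

from sichml.cohort import Outcome, generate_cohort

records, truths = generate_cohort(n_sich=16, n_control=100, seed=1)

sich = np.array([r.outcome == Outcome.SICH for r in records])
nihss = np.array([r.nihss for r in records], dtype=float)
ischemia = np.array([t.ischemia_present for t in truths])
hyper = np.array([t.hyperdense_mca for t in truths])

print(f"cohort: {len(records)} subjects, {sich.sum()} SICH")
print(f"NIHSS mean          SICH {nihss[sich].mean():5.1f}   "
      f"no SICH {nihss[~sich].mean():5.1f}")
print(f"acute ischemia      SICH {100 * ischemia[sich].mean():4.0f}%   "
      f"no SICH {100 * ischemia[~sich].mean():4.0f}%")
print(f"hyperdense MCA      SICH {100 * hyper[sich].mean():4.0f}%   "
      f"no SICH {100 * hyper[~sich].mean():4.0f}%")
print()
print("Cases carry more severe strokes and more visible ischemia than")
print("controls, as in the clinical population the model emulates; the")
print("contrasts emerge from the risk model, not from per-group sampling.")
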