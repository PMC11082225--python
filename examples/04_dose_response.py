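"""Fit a 4PL dose-response for the BIM peptide and derive EC50/EC90.

A primed sample reaches 90% cyt c loss at a low dose; an unprimed one whose
plateau stays below 90% gets a typed NOT_REACHED instead of a number.
"""

import numpy as np

from bh3flow import NOT_REACHED, ec_fraction, fit_4pl
from bh3flow.presets import FourPLTruth

doses = np.logspace(-3, 1, 8)        # 0.001 - 10 uM
rng = np.random.default_rng(4)

for label, truth in [
    ("primed (CLL-like)", FourPLTruth(0, 100, np.log10(0.08 / 9), 1.0)),
    ("unprimed (RS-like)", FourPLTruth(0, 65, np.log10(0.5), 1.0)),
]:
    responses = truth.response(doses) + rng.normal(0, 3, doses.size)
    fit = fit_4pl(doses, responses)
    ec90 = ec_fraction(fit, 90)
    ec90_txt = "NOT_REACHED" if ec90 is NOT_REACHED else f"{ec90:.3f} uM"
    print(f"{label}: top {fit.top:5.1f} %, hill {fit.hill:4.2f}, "
          f"EC50 {fit.ec50:.4f} uM, EC90 {ec90_txt}")
print("EC90 is the dose attaining 90% loss on the fitted curve; a plateau")
print("below 90% (or a dose beyond the tested range) reports NOT_REACHED,")
print("the signature of samples with unprimed subpopulations.")
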