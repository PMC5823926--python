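"""Spatial patterning on a 24-quadrant membrane row.

Two experiments: (i) opposed external HSL gradients spotted one quadrant
beyond each row end; (ii) programmed emergence with two adjacent sender
populations (LuxI left, LasI right) induced by arabinose.  Both are
background-corrected against matched uninduced membranes, profiled, and the
RFP interface domain is called.  The sender run also estimates the effective
3OC6HSL concentration from uniform-HSL standard curves.
"""
import numpy as np

from hslpattern import patternscan
from hslpattern.circuitsim import (Condition, GridSpec, parameter_set,
                                   sender_grid, simulate_membrane)

params = parameter_set("and_rbs250")

# (i) opposed spotted gradients (500 uM 3OC6HSL left, 200 uM 3OC12HSL right)
spotted = simulate_membrane(params, GridSpec(), "spotted")
blank = simulate_membrane(params, GridSpec(), "uniform", Condition())
prof = patternscan.position_profile(spotted, blank, 3000.0)
call = patternscan.detect_interface_domain(prof, "RFP")
print("opposed gradients: RFP domain quadrants "
      f"[{call.start}, {call.end}], peak {call.peak}, "
      f"symmetry {call.symmetry:.2f} (flat central plateau)")

# (ii) programmed emergence from sender populations
induced = simulate_membrane(params, sender_grid(), "senders",
                            Condition(arabinose=25.0))
control = simulate_membrane(params, sender_grid(), "senders",
                            Condition(arabinose=0.0))
prof = patternscan.position_profile(induced, control, 3000.0)
call = patternscan.detect_interface_domain(prof, "RFP")
left_peak = int(np.argmax(prof.mean["RFP"][:12])) + 1
print("sender populations: RFP domain quadrants "
      f"[{call.start}, {call.end}], peak {call.peak}, "
      f"symmetry {call.symmetry:.2f}; left-half maximum at quadrant "
      f"{left_peak} (boundary between 12 and 13)")

# effective 3OC6HSL at the quadrant farthest from the interface
standards = {}
ctl_u = simulate_membrane(params, GridSpec(), "uniform", Condition())
for c in (0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0):
    ms = simulate_membrane(params, GridSpec(), "uniform", Condition(c6=c))
    standards[c] = float(
        patternscan.position_profile(ms, ctl_u, 3000.0).mean["CFP"].mean())
est = patternscan.estimate_effective_hsl(float(prof.mean["CFP"][0]), standards)
print(f"effective 3OC6HSL at quadrant 1: ~{est.point:.2f} uM "
      f"(bracket [{est.low}, {est.high}] uM) - a sub-micromolar level,")
print("even though the senders were induced with 25 mM arabinose.")
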