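"""Quantify T7RNAP activity with the ratiometric reporter.

Simulates an IPTG titration of the best reporter configuration (mutant T7
promoter, reference RBS, low-copy backbone) in three replicates, detects the
exponential growth phase per well, computes the mean YFP/CFP ratio, and fits
the fold-induction dose-response.
"""
import warnings

from hslpattern.circuitsim import (IPTG_LEVELS, Condition, parameter_set,
                                   simulate_plate)
from hslpattern.ratiometrics import titration_max_fold

warnings.filterwarnings("ignore", message="Covariance of the parameters")

params = parameter_set("reporter_best")
layout = [(Condition(iptg=c), "ratiometric_reporter") for c in IPTG_LEVELS]
plate = simulate_plate(params, layout, replicates=3, seed=1)
fit = titration_max_fold(plate, inducer="iptg")

print("IPTG [mM]   mean fold-induction")
for c, f in zip(fit.concentrations, fit.mean_folds):
    print(f"{c:9.3g}   {f:6.2f}")
print(f"\nmaximum fold-induction : {fit.max_fold:.2f} +/- {fit.max_fold_sd:.2f}"
      " (between-day s.d.)")
print(f"half-max IPTG          : {fit.half_max_conc:.3f} mM")
print(f"Hill coefficient       : {fit.hill_coef:.2f}")
print("\nThe fold-induction is the YFP/CFP ratio during exponential growth,")
print("relative to the uninduced wells; the generator's ground truth for")
print("this reporter is 7.58-fold, so the fit should land within a few %.")
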