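"""Incidental activity and dose from a radioactive treatment beam, plus
the variance-based sample-size (convergence) study.

Every stopped C11 primary eventually decays inside the patient; the
extra dose is the positron kinetic energy plus the locally absorbed
fraction of the two 511 keV annihilation photons.
"""

import numpy as np

from ribpet import SPECIES, convergence_study, incidental_dose

# 2.3e11 C11 ions in a 10 cm cubic treatment volume
rep = incidental_dose(2.3e11, SPECIES["C11"], volume=1000.0)
print(f"initial activity concentration: "
      f"{rep.activity_concentration:.3f} MBq/cc")
print(f"decay dose: {rep.decay_dose:.1f} mSv over all decays")
print("assumptions:", rep.assumptions)


# How many samples does a Monte Carlo estimate need?  Double N until the
# spread over 50 replicates drops below 1% of the mean.
def toy_estimator(seed: int, n: int) -> float:
    rng = np.random.default_rng(seed)
    return float(rng.exponential(2.0, n).mean())


N, trace = convergence_study(toy_estimator, M=50, threshold=0.01,
                             n_start=64, seed=3)
print(f"\nconvergence study: N = {N} samples reach SD/mean < 1%")
for n, ratio in trace:
    print(f"  N = {n:6d}: SD/mean = {100 * ratio:.2f}%")
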