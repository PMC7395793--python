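"""Concentration-invariant piriform readout (feedback circuit variant).

Trains the coupled bulb + piriform circuit, then presents single learned
odors at concentrations 0.1-2.0 and compares how much the granule rates
(concentration code) and the piriform rates (presence code) vary.
"""

import warnings

import numpy as np

from olfbayes import SimConfig, concentration_sweep, train_unsupervised

# odors no cell has claimed yield all-NaN response rows; that is expected
warnings.filterwarnings("ignore", message="Mean of empty slice")
warnings.filterwarnings("ignore", message="Degrees of freedom")

config = SimConfig(M=20, N=100, c_o=0.15, dt=4.0, T_max=3000.0, steady_tol=5e-5, dyn_dtype="float32")
res = train_unsupervised(config, seed=1, n_trials=600,
                         variant="local_lateral_feedback")

conc, g, p = concentration_sweep(res["bulb"], res["piriform"], res["world"])


def cv(a):
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.nanstd(a, axis=0) / np.nanmean(a, axis=0)


cv_g, cv_p = np.nanmedian(cv(g)), np.nanmedian(cv(p))
print("concentrations presented:", np.round(conc, 2))
print(f"median CV across concentrations, granule cells : {cv_g:.3f}")
print(f"median CV across concentrations, piriform cells: {cv_p:.3f}")
print(f"ratio piriform/granule: {cv_p / cv_g:.3f}")
print()
print("Granule rates track the presented concentration (large CV), while the")
print("piriform presence probabilities saturate once the odor is detected")
print("(small CV) - the concentration-invariant code that downstream reward")
print("learning relies on.")
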