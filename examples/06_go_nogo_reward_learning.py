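"""Odor-reward association: the go/no-go task.

Pretrains a small ensemble of circuits without reward, freezes them, then
lets the reward-prediction neuron learn which of two odors pays off.
(The headline-scale run - M=50, N=200, 50 simulations - is what
scripts/acceptance.py reproduces; this demo uses a lighter ensemble.)
"""

import numpy as np

from olfbayes import SimConfig
from olfbayes.experiments import run_go_nogo_experiment

config = SimConfig(M=50, N=200, dt=4.0, T_max=3000.0, steady_tol=5e-5, dyn_dtype="float32")
out = run_go_nogo_experiment(seed=3, n_sims=8, n_pretrain=800,
                             n_reward_trials=12, config=config)

print("reward trial   classification performance   average error")
for k, (p, e) in enumerate(zip(out["performance"], out["average_error"]), 1):
    print(f"{k:12d}   {p:25.3f}   {e:13.3f}")
print()
print("Performance is the fraction of simulations whose pre-reward prediction")
print("-e_p falls on the same side of 0.5 as the delivered reward; the error")
print("is the RMS gap between prediction and reward.  Association through the")
print("concentration-invariant piriform code is learned within a handful of")
print("trials because each rewarded odor maps to a near-binary presence code.")
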