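"""Exact loss curve vs full-batch gradient descent on one random task.

Builds a small whitened task and a zero-balanced random init, solves the
closed-form dynamics, runs discrete gradient descent at eta = 5e-4, and
prints the worst disagreement between the two loss curves.
"""

import numpy as np

import lindyn as ld
from lindyn.experiments import draw_compatible_init
from lindyn.simulate import SimConfig, simulate_gd

eta = 5e-4
tau = 1.0 / eta

data = ld.make_random_whitened_task(Ni=4, No=4, seed=0)
corr = ld.compute_correlations(data)
svd = ld.compact_svd(corr.Sigma_yx)
init = draw_compatible_init(svd, 4, 4, 5, scale=0.3,
                            rng=np.random.default_rng(1))

steps = int(30 * tau / svd.Stilde.min())
sim = simulate_gd(init, data, SimConfig(eta=eta, steps=steps,
                                        record_stride=steps // 200))
ana = ld.exact_qqt(init, svd, sim.times[1:], tau)

sim_loss = ld.loss_curve(sim, corr)
ana_loss = ld.loss_curve(ana, corr)
dev = np.abs(ana_loss - sim_loss[1:]).max()

print(f"initial loss          : {sim_loss[0]:.4f}")
print(f"final loss (GD)       : {sim_loss[-1]:.2e}")
print(f"final loss (analytic) : {ana_loss[-1]:.2e}")
print(f"max |analytic - GD|   : {dev:.2e}")
print("The closed form reproduces the whole gradient-descent loss curve; the")
print("residual is the O(eta) discretisation error of gradient descent itself.")
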