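"""Reversal learning: a saddle separatrix in deep nets, absent in shallow ones.

Initialising a two-layer network at the negated task function puts gradient
flow exactly on the separatrix of a saddle: the alignment matrix B is
singular, the analytic flow converges to zero function, and simulated
gradient descent slows catastrophically.  A shallow network relearns the
reversed task with a plain exponential.
"""

import numpy as np

import lindyn as ld
from lindyn.experiments import ExperimentConfig, run_experiment

summary = run_experiment(ExperimentConfig(
    experiment="reversal", seed=0, out_dir="scratch/reversal_example"))
c = summary["checks"]

print(f"min singular value of B at the reversal init : "
      f"{c['b_singular_and_error_raised']['value']:.2e}")
print(f"GD slowdown vs matched random init           : "
      f"{c['saddle_slowdown_ratio']['value']:.1f}x")
print(f"analytic function norm ratios (eps 1e-4,-6,-8): "
      + ", ".join(f"{v:.2e}" for v in c['eps_fallback_norms_decrease']['value']))
print(f"shallow network final residual               : "
      f"{c['shallow_converges']['value']:.2e}")
print("As the perturbation vanishes the deep analytic solution collapses to")
print("the saddle (function -> 0); only noise lets simulations escape, and")
print("shallow networks never see the saddle at all.")
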