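"""Cross-mode coupling in the 2x2 aligned setting: transient peak and sigmoid.

For an aligned initialisation with cross-coupling b(0), the off-diagonal of
A^T A(t) rises to a transient peak before decaying to zero.  The printed
peak-time formula is compared against a dense grid search, and the
small-init sigmoidal mode against the full aligned solution.
"""

import numpy as np

import lindyn as ld
from lindyn.riccati import TwoByTwoInit

tau, s = 1.0, 1.0
init2 = TwoByTwoInit(a1=0.02, a2=0.03, b0=0.015, s1=s, s2=s)

t_peak = ld.two_by_two_offdiag_peak(init2, tau)
grid = np.linspace(1e-4, 8.0, 4000)
atats = ld.aligned_dynamics(init2.gram, np.array([s, s]), grid, tau)
b_abs = np.array([abs(A[0, 1]) for A in atats])
print(f"peak time (formula)     : {t_peak:.4f} tau")
print(f"peak time (grid argmax) : {grid[np.argmax(b_abs)]:.4f} tau")
print(f"coupling b: {init2.b0:.3f} -> peak {b_abs.max():.3f} -> "
      f"final {b_abs[-1]:.2e}")

a0 = 0.01
b0 = a0 * (1 - 1e-6)
times = np.linspace(1e-3, 5.0, 500)
sig = ld.sigmoid_mode(a0, a0, s, times, tau)
full = ld.aligned_dynamics(np.array([[a0, b0], [b0, a0]]),
                           np.array([s, s]), times, tau)
err = np.abs(sig - [A[0, 0] for A in full]).max()
print(f"sigmoid mode vs full aligned solution: max err {err:.2e}")
print("The misaligned coupling is transiently amplified and then removed;")
print("small (rank-one) inits follow the classic sigmoidal trajectory.")
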