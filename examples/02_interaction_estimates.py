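"""Estimate a community's interaction matrix from its abundance series.

The overall interaction strength of member j on member i is estimated
as J_ij = Cov(f_i, z_j) over a time window, where f_i = dz_i/dt; the
per-capita strength is a_ij = Cov(phi_i, z_j) with phi_i = f_i / z_i.
Eigenvalues of J classify the window as stable/unstable and
oscillatory/non-oscillatory.
"""

import numpy as np

from dcmkit import (
    TimeGrid,
    classify_stability,
    eigen_decompose,
    jacobian_trajectory,
    make_switch_scenario,
    simulate_glv,
)

model = make_switch_scenario(n_species=5, switch_time=20.0, seed=1)
series = simulate_glv(model, TimeGrid.regular(0.0, 40.0, 0.5), 0.01)

trajectory = jacobian_trajectory(series, min_points=3)
print(f"{len(trajectory)} expanding windows, each yielding a 5x5 J and A")

final = trajectory[-1]
np.set_printoptions(precision=3, suppress=True)
print("\nJ over the full series (Cov(f_i, z_j)):")
print(final.J)

label = classify_stability(eigen_decompose(final))
lam = label.leading_eigenvalue
print(f"\nleading eigenvalue: {lam.real:.4f} {lam.imag:+.4f}i")
print(f"unstable: {label.is_unstable}, oscillatory: {label.is_oscillatory}")
print("(a positive real part means perturbations grow; a nonzero imaginary")
print(" part means the community dynamics have an oscillatory component)")
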