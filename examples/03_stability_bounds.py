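"""Step-size stability bounds of the three schemes, analytic and empirical.

For the all-to-all inhibitory network the drift spectrum is known in
closed form, so each scheme's largest stable step follows from its zeta
stability function.  The empirical check simulates on a halving grid and
flags steps whose error against the exact solution exceeds 1e10.
"""

import numpy as np

import ratenet as rn

N = 400
eigs = rn.all_to_all_eigenvalues(N)
print(f"all-to-all inhibitory network, N = {N}: lambda_max = {eigs[0]:.0f}\n")

net = rn.build_all_to_all_inhibitory(N)
grid = [0.4, 0.2, 0.1, 0.05, 0.025]
print(f"{'scheme':20} {'closed-form dt_max':>19} {'empirical (grid)':>17}")
for method in ["euler_maruyama", "implicit_euler", "exponential_euler"]:
    closed = rn.max_stable_ratio(method, eigs).x_max
    emp = rn.empirical_stability_bound(net, method, grid, T=50.0, seed=1)
    print(f"{method:20} {closed:19.4f} {emp['largest_stable_dt']:>17}")

print()
print("unconditional stability threshold |lambda| <=",
      rn.unconditional_stability_threshold("exponential_euler"))
raw, rounded = rn.ie_exp_crossover()
print(f"exponential Euler overtakes implicit Euler at |lambda| = {raw:.4f} "
      f"(~{rounded})")

# Below |lambda| = 2 the implicit and exponential Euler schemes never
# become unstable; beyond ~2.8 the exponential Euler allows the larger
# step of the two.
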