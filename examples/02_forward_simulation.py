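"""Run the discretized reaction-diffusion model forward and check invariants.

Shows the forward-Euler solver with the nine-point Laplacian on two textbook
cases: pure proliferation (exact compounding) and pure diffusion on a
periodic domain (conservation of total intensity).
"""

import numpy as np

from petpde import (
    Grid2D,
    Quantity,
    ReactionDiffusionParams,
    ScalarField2D,
    linear_kill_response,
    simulate_forward,
)

grid = Grid2D(32, 32, 2.5, 2.5)
zeros = ScalarField2D(grid, np.zeros(grid.shape), Quantity.DOSE_GY)

# pure proliferation: U(T) = U0 * (1 + h*beta)^Nt exactly
U0 = ScalarField2D(grid, np.ones(grid.shape), Quantity.SUV)
params = ReactionDiffusionParams(alpha=0.0, beta=1.0, n_steps=4, total_time=1.0)
traj = simulate_forward(U0, zeros, params)
print(f"pure proliferation, beta=1, Nt=4, h=0.25:")
print(f"  final value {traj.final.values[0, 0]:.8f}  (closed form 1.25^4 = {1.25**4})")

# pure diffusion, periodic boundary: total intensity is conserved
rng = np.random.default_rng(0)
U0 = ScalarField2D(grid, rng.uniform(0, 3, grid.shape), Quantity.SUV)
params = ReactionDiffusionParams(
    alpha=0.2, beta=0.0, n_steps=8, total_time=1.0, boundary="periodic"
)
traj = simulate_forward(U0, zeros, params)
drift = abs(traj.final.values.sum() - U0.values.sum()) / U0.values.sum()
print(f"pure diffusion, periodic boundary:")
print(f"  relative drift of total intensity over 8 steps: {drift:.2e}")

# dose-coupled kill: intermediate states interpolate pre -> post
dose = ScalarField2D(grid, np.full(grid.shape, 10.0), Quantity.DOSE_GY)
params = ReactionDiffusionParams(alpha=0.0, beta=0.0, n_steps=4, total_time=1.0)
traj = simulate_forward(U0, dose, params, linear_kill_response(0.2))
means = [f.values.mean() for f in traj.frames]
print("linear kill (gamma=0.2, 10 Gy): mean SUV per time step")
for t, m in zip(traj.times, means):
    print(f"  t={t:.2f}  mean={m:.4f}")
print("Each step multiplies the state by (1 - h*gamma*dose) = 0.5, so the")
print("mean halves per step: the model resolves the transition, not only the endpoint.")
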