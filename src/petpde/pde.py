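"""Discretized dose-coupled reaction-diffusion dynamics.

The model describes post-radiotherapy change of the SUV field U as

    U_t = alpha * Laplacian(U) + beta * U + F(D o U)

where alpha is a diffusion coefficient, beta a proliferation rate, D the
planned dose map and F a response operator acting on the element-wise
product psi = D o U. Time integration is explicit forward Euler:

    U^{n+1} = U^n + h * G(U^n) + h * F(D o U^n),   G(U) = alpha*Lap(U) + beta*U

with h = T / Nt. The Laplacian is the nine-point stencil

    [[1/4, 1/2, 1/4],
     [1/2,  -3, 1/2],
     [1/4, 1/2, 1/4]]

applied in pixel units (grid spacing is absorbed into alpha, so alpha values
are comparable only at fixed spacing).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import numpy as np

from .grid import Quantity, ScalarField2D, write_field

#: Nine-point finite-difference Laplacian stencil (pixel units).
LAPLACIAN_STENCIL = np.array(
    [[0.25, 0.5, 0.25], [0.5, -3.0, 0.5], [0.25, 0.5, 0.25]]
)

Boundary = Literal["replicate", "periodic", "zero"]

#: Explicit-Euler stability bound for the nine-point stencil: update weights
#: stay nonnegative while h*alpha <= 1/3.
STABILITY_LIMIT = 1.0 / 3.0


@dataclass(frozen=True)
class ReactionDiffusionParams:
    """Coefficients and time discretization of the reaction-diffusion model.

    alpha : diffusion coefficient (pixel^2 per unit time), >= 0
    beta  : proliferation rate (per unit time), any sign
    n_steps : number of forward-Euler steps Nt
    total_time : final time T; the step is h = T / Nt
    """

    alpha: float = 0.05
    beta: float = 0.0
    n_steps: int = 4
    total_time: float = 1.0
    boundary: Boundary = "replicate"

    def __post_init__(self) -> None:
        if self.alpha < 0 or not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite and >= 0")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.total_time <= 0:
            raise ValueError("total_time must be positive")
        if self.h * self.alpha > STABILITY_LIMIT:
            warnings.warn(
                f"h*alpha = {self.h * self.alpha:.4g} exceeds the explicit-Euler "
                f"stability bound 1/3; the simulation may oscillate or diverge",
                stacklevel=2,
            )

    @property
    def h(self) -> float:
        return self.total_time / self.n_steps


class ResponseOperator:
    """A pointwise/field operator mapping psi = D o U to a response field."""

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], label: str):
        self._fn = fn
        self.label = label

    def __call__(self, psi: np.ndarray) -> np.ndarray:
        psi = np.asarray(psi, dtype=float)
        out = np.asarray(self._fn(psi), dtype=float)
        if out.shape != psi.shape:
            raise ValueError(
                f"response operator {self.label!r} changed shape "
                f"{psi.shape} -> {out.shape}"
            )
        return out

    def __repr__(self) -> str:
        return f"ResponseOperator({self.label!r})"


ZERO_RESPONSE = ResponseOperator(lambda psi: np.zeros_like(psi), "zero")


def linear_kill_response(gamma: float) -> ResponseOperator:
    """Linear cell-kill operator psi -> -gamma * psi (first-order kill)."""
    if not np.isfinite(gamma) or gamma < 0:
        raise ValueError("gamma must be finite and >= 0")
    return ResponseOperator(lambda psi: -gamma * psi, f"linear_kill(gamma={gamma})")


def saturating_kill_response(gamma: float, psi_half: float) -> ResponseOperator:
    """Saturating kill psi -> -gamma*psi / (1 + psi/psi_half).

    The magnitude is bounded by gamma*psi_half for any psi >= 0, emulating a
    response that plateaus at high dose-uptake product.
    """
    if not np.isfinite(gamma) or gamma < 0:
        raise ValueError("gamma must be finite and >= 0")
    if not np.isfinite(psi_half) or psi_half <= 0:
        raise ValueError("psi_half must be finite and > 0")
    return ResponseOperator(
        lambda psi: -gamma * psi / (1.0 + psi / psi_half),
        f"saturating_kill(gamma={gamma}, psi_half={psi_half})",
    )


# ---------------------------------------------------------------------------
# Nine-point Laplacian
# ---------------------------------------------------------------------------

def _pad(U: np.ndarray, boundary: Boundary) -> np.ndarray:
    pad = [(0, 0)] * (U.ndim - 2) + [(1, 1), (1, 1)]
    if boundary == "replicate":
        return np.pad(U, pad, mode="edge")
    if boundary == "periodic":
        return np.pad(U, pad, mode="wrap")
    if boundary == "zero":
        return np.pad(U, pad, mode="constant")
    raise ValueError(f"unknown boundary {boundary!r}")


def discrete_laplacian(U: np.ndarray, boundary: Boundary = "replicate") -> np.ndarray:
    """Nine-point Laplacian of a 2D field (or a stack of fields).

    Works on arrays of shape (..., H, W); the stencil is applied to the last
    two axes with the chosen boundary rule.
    """
    U = np.asarray(U, dtype=float)
    if U.shape[-2] < 3 or U.shape[-1] < 3:
        raise ValueError(f"field must be at least 3x3, got shape {U.shape}")
    if not np.all(np.isfinite(U)):
        raise ValueError("field must be finite")
    P = _pad(U, boundary)
    out = np.zeros_like(U)
    for di in range(3):
        for dj in range(3):
            w = LAPLACIAN_STENCIL[di, dj]
            out += w * P[..., di : di + U.shape[-2], dj : dj + U.shape[-1]]
    return out


def discrete_laplacian_adjoint(
    g: np.ndarray, boundary: Boundary = "replicate"
) -> np.ndarray:
    """Adjoint of :func:`discrete_laplacian` as a linear map on fields.

    For the symmetric stencil with periodic boundary the operator is
    self-adjoint; replicate and zero padding break exact self-adjointness at
    the border, and this routine accounts for the fold-back of padded rows
    and columns. Used by gradient-based training.
    """
    g = np.asarray(g, dtype=float)
    H, W = g.shape[-2], g.shape[-1]
    gp = np.zeros(g.shape[:-2] + (H + 2, W + 2), dtype=float)
    for di in range(3):
        for dj in range(3):
            gp[..., di : di + H, dj : dj + W] += LAPLACIAN_STENCIL[di, dj] * g
    out = gp[..., 1:-1, 1:-1].copy()
    if boundary == "replicate":
        out[..., 0, :] += gp[..., 0, 1:-1]
        out[..., -1, :] += gp[..., -1, 1:-1]
        out[..., :, 0] += gp[..., 1:-1, 0]
        out[..., :, -1] += gp[..., 1:-1, -1]
        out[..., 0, 0] += gp[..., 0, 0]
        out[..., 0, -1] += gp[..., 0, -1]
        out[..., -1, 0] += gp[..., -1, 0]
        out[..., -1, -1] += gp[..., -1, -1]
    elif boundary == "periodic":
        out[..., 0, :] += gp[..., -1, 1:-1]
        out[..., -1, :] += gp[..., 0, 1:-1]
        out[..., :, 0] += gp[..., 1:-1, -1]
        out[..., :, -1] += gp[..., 1:-1, 0]
        out[..., 0, 0] += gp[..., -1, -1]
        out[..., 0, -1] += gp[..., -1, 0]
        out[..., -1, 0] += gp[..., 0, -1]
        out[..., -1, -1] += gp[..., 0, 0]
    elif boundary != "zero":
        raise ValueError(f"unknown boundary {boundary!r}")
    return out


def diffusion_proliferation(
    U: np.ndarray, params: ReactionDiffusionParams
) -> np.ndarray:
    """The operator G(U) = alpha * Laplacian(U) + beta * U."""
    return params.alpha * discrete_laplacian(U, params.boundary) + params.beta * np.asarray(
        U, dtype=float
    )


def euler_step(
    U: np.ndarray,
    D: np.ndarray,
    params: ReactionDiffusionParams,
    response: ResponseOperator = ZERO_RESPONSE,
) -> np.ndarray:
    """One forward-Euler update U + h*G(U) + h*F(D o U)."""
    U = np.asarray(U, dtype=float)
    D = np.asarray(D, dtype=float)
    if U.shape != D.shape:
        raise ValueError(f"U shape {U.shape} and D shape {D.shape} differ")
    h = params.h
    return U + h * diffusion_proliferation(U, params) + h * response(D * U)


@dataclass
class Trajectory:
    """All Nt+1 states of a forward simulation, frames[0] being the input."""

    frames: list[ScalarField2D]
    times: list[float]

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.times):
            raise ValueError("frames and times must have equal length")

    @property
    def final(self) -> ScalarField2D:
        return self.frames[-1]

    def export(self, out_dir: str | Path, params: dict | None = None) -> None:
        """One NIfTI per frame plus a JSON manifest of times and parameters."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        names = []
        for i, f in enumerate(self.frames):
            name = f"frame_{i:03d}.nii.gz"
            write_field(out / name, f)
            names.append(name)
        manifest = {"times": list(map(float, self.times)), "frames": names}
        if params:
            manifest["params"] = params
        (out / "trajectory.json").write_text(json.dumps(manifest, indent=2))


def simulate_forward(
    U0: ScalarField2D,
    D: ScalarField2D,
    params: ReactionDiffusionParams,
    response: ResponseOperator = ZERO_RESPONSE,
    clip_negative: bool = False,
) -> Trajectory:
    """Iterate the Euler update for Nt steps from the initial state U0.

    ``clip_negative`` projects each state onto [0, inf) after every step; the
    plain update rule has no projection, so this is off by default and exists
    for phantom generation where SUV must stay physical.
    """
    if U0.grid != D.grid:
        raise ValueError("U0 and D must live on the same grid")
    h = params.h
    U = U0.values.copy()
    frames = [U0.with_values(U.copy())]
    times = [0.0]
    for n in range(params.n_steps):
        # overflow here is not an error condition: it surfaces as the
        # divergence check below
        with np.errstate(over="ignore", invalid="ignore"):
            U = euler_step(U, D.values, params, response)
        if clip_negative:
            np.maximum(U, 0.0, out=U)
        if not np.all(np.isfinite(U)):
            raise FloatingPointError(
                f"simulation diverged (non-finite values) at step {n + 1}"
            )
        # a state that dipped negative is model state, no longer a physical SUV
        q = U0.quantity if U.min() >= 0 else Quantity.DIMENSIONLESS
        frames.append(ScalarField2D(U0.grid, U.copy(), q))
        times.append((n + 1) * h)
    return Trajectory(frames, times)
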