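"""The two-branch unrolled model: learned response + diffusion-proliferation.

One branch is the convolutional response network applied to psi = D o U; the
other applies G(U) = alpha*Lap(U) + beta*U with two trainable scalars. Both
are merged by the forward-Euler update and unrolled for Nt steps with shared
network weights, producing the predicted post-radiation image together with
the intermediate states and a breakdown of the three accumulated biological
effects (diffusion, proliferation, dose response).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..grid import Quantity, ScalarField2D
from ..pde import (
    ReactionDiffusionParams,
    ResponseOperator,
    Trajectory,
    discrete_laplacian,
    euler_step,
)
from .layers import softplus, softplus_inverse
from .response_net import ResponseNet, ResponseNetConfig


@dataclass(frozen=True)
class Normalization:
    """Fixed input/output scaling applied before the network sees the data.

    SUV is divided by ``suv_scale`` and dose by ``dose_scale`` (the delivered
    maximum). The PDE coefficients alpha and beta multiply U linearly, so
    uniform SUV scaling leaves them unchanged; the network absorbs the dose
    scaling into the learned operator.
    """

    suv_scale: float = 10.0
    dose_scale: float = 20.0

    def __post_init__(self) -> None:
        if self.suv_scale <= 0 or self.dose_scale <= 0:
            raise ValueError("normalization scales must be positive")


@dataclass
class Breakdown:
    """Per-pixel biological-effect maps accumulated over the Nt steps.

    ``diffusion + proliferation + dose_response`` telescopes to the total
    change ``prediction - input`` (same units as U).
    """

    diffusion: np.ndarray
    proliferation: np.ndarray
    dose_response: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.diffusion + self.proliferation + self.dose_response


@dataclass
class TrainedModel:
    """Weights, PDE coefficients and configuration of a trained predictor."""

    net: ResponseNet
    alpha_raw: float  # alpha = softplus(alpha_raw) >= 0
    beta: float
    pde: ReactionDiffusionParams
    normalization: Normalization = field(default_factory=Normalization)
    training_history: list[dict] = field(default_factory=list)

    @property
    def alpha_hat(self) -> float:
        return softplus(self.alpha_raw)

    @property
    def beta_hat(self) -> float:
        return self.beta

    def pde_params(self) -> ReactionDiffusionParams:
        return ReactionDiffusionParams(
            alpha=self.alpha_hat,
            beta=self.beta,
            n_steps=self.pde.n_steps,
            total_time=self.pde.total_time,
            boundary=self.pde.boundary,
        )

    def response_operator(self) -> ResponseOperator:
        """The learned network wrapped as a field-level response operator."""
        return ResponseOperator(self.net.predict_field, "learned")


def initial_model(
    net_cfg: ResponseNetConfig | None = None,
    pde: ReactionDiffusionParams | None = None,
    normalization: Normalization | None = None,
    alpha_init: float = 0.01,
    beta_init: float = 0.0,
    seed: int = 0,
    dtype=np.float32,
) -> TrainedModel:
    """An untrained model: zero response operator, G with the initial alpha, beta."""
    net = ResponseNet(net_cfg or ResponseNetConfig(), seed=seed, dtype=dtype)
    return TrainedModel(
        net=net,
        alpha_raw=softplus_inverse(alpha_init),
        beta=beta_init,
        pde=pde or ReactionDiffusionParams(),
        normalization=normalization or Normalization(),
    )


def recover_coefficients(model: TrainedModel) -> tuple[float, float]:
    """The fitted (alpha_hat, beta_hat) on the physical per-unit-time scale.

    G is linear in U, so the uniform SUV normalization cancels and the raw
    fitted scalars are already physical.
    """
    return model.alpha_hat, model.beta_hat


def forward_unrolled(
    model: TrainedModel,
    pre: ScalarField2D,
    dose: ScalarField2D,
    response: ResponseOperator | None = None,
) -> tuple[ScalarField2D, Trajectory, Breakdown]:
    """Predict the post-radiation image by unrolling the Euler update.

    Runs on the normalized scale and de-normalizes the outputs to SUV units.
    ``response`` substitutes an analytic operator for the network (used for
    cross-checks against the plain PDE solver); by default the learned
    network in inference mode is used.
    """
    if pre.grid != dose.grid:
        raise ValueError("pre and dose must live on the same grid")
    norm = model.normalization
    params = model.pde_params()
    F = response if response is not None else model.response_operator()

    U = pre.values / norm.suv_scale
    D = dose.values / norm.dose_scale
    h = params.h
    su = norm.suv_scale

    diff = np.zeros_like(U)
    prol = np.zeros_like(U)
    resp = np.zeros_like(U)
    frames = [ScalarField2D(pre.grid, U * su, Quantity.SUV)]
    times = [0.0]
    for n in range(params.n_steps):
        if response is None:
            # learned operator with the batch-norm statistics of this step
            step_F = ResponseOperator(
                lambda psi, _n=n: model.net.predict_field(psi, step=_n), "learned"
            )
        else:
            step_F = F
        lap = discrete_laplacian(U, params.boundary)
        r = step_F(D * U)
        diff += h * params.alpha * lap
        prol += h * params.beta * U
        resp += h * r
        U = euler_step(U, D, params, step_F)
        if not np.all(np.isfinite(U)):
            raise FloatingPointError(f"unrolled prediction diverged at step {n + 1}")
        q = Quantity.SUV if U.min() >= 0 else Quantity.DIMENSIONLESS
        frames.append(ScalarField2D(pre.grid, U * su, q))
        times.append((n + 1) * h)

    prediction = frames[-1]
    trajectory = Trajectory(frames, times)
    breakdown = Breakdown(diff * su, prol * su, resp * su)
    return prediction, trajectory, breakdown


# ---------------------------------------------------------------------------
# Checkpointing: single weights file + JSON sidecar
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write weights to ``<path>`` (npz) and metadata to ``<path>.json``."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    state = model.net.state_dict()
    np.savez(path, **state)
    sidecar = {
        "alpha_raw": model.alpha_raw,
        "alpha_hat": model.alpha_hat,
        "beta": model.beta,
        "net_config": model.net.config.__dict__,
        "pde": {
            "alpha": model.pde.alpha,
            "beta": model.pde.beta,
            "n_steps": model.pde.n_steps,
            "total_time": model.pde.total_time,
            "boundary": model.pde.boundary,
        },
        "normalization": {
            "suv_scale": model.normalization.suv_scale,
            "dose_scale": model.normalization.dose_scale,
        },
        "training_history": model.training_history,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path, dtype=np.float32) -> TrainedModel:
    path = Path(path)
    weights_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = json.loads(Path(str(weights_path) + ".json").read_text())
    cfg = ResponseNetConfig(**sidecar["net_config"])
    net = ResponseNet(cfg, seed=0, dtype=dtype)
    with np.load(weights_path) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return TrainedModel(
        net=net,
        alpha_raw=sidecar["alpha_raw"],
        beta=sidecar["beta"],
        pde=ReactionDiffusionParams(**sidecar["pde"]),
        normalization=Normalization(**sidecar["normalization"]),
        training_history=sidecar.get("training_history", []),
    )
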