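"""Joint training of the response network and the two PDE coefficients.

The l2 loss between the unrolled Nt-step prediction and the ground-truth
post image is minimized over the network weights theta together with alpha
(through a softplus transform, keeping the diffusion coefficient
nonnegative) and beta, using Adam with mini-batches. Gradients flow through
every unrolled step: through the network at each application of psi = D o U,
and through the linear operator G via the exact adjoint of the nine-point
Laplacian.

Early stopping monitors the validation loss; the returned model carries the
weights of the best validation epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..grid import PairedCase
from ..pde import ReactionDiffusionParams, discrete_laplacian, discrete_laplacian_adjoint
from .layers import sigmoid, softplus, softplus_inverse
from .model import Normalization, TrainedModel
from .response_net import ResponseNet, ResponseNetConfig


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization protocol: batching, epochs, early stopping, seeding."""

    batch_size: int = 10
    max_epochs: int = 400
    patience: int = 100
    learning_rate: float = 1e-3
    coefficient_learning_rate: float = 1e-2
    lr_plateau_patience: int = 8
    lr_plateau_factor: float = 0.5
    seed: int = 0
    deterministic: bool = True
    alpha_init: float = 0.01
    beta_init: float = 0.0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.learning_rate <= 0 or self.coefficient_learning_rate <= 0:
            raise ValueError("learning rates must be positive")
        if not (0 < self.lr_plateau_factor <= 1):
            raise ValueError("lr_plateau_factor must be in (0, 1]")
        if self.lr_plateau_patience < 1:
            raise ValueError("lr_plateau_patience must be >= 1")


def l2_loss(predictions: Sequence[np.ndarray], truths: Sequence[np.ndarray]) -> float:
    """Mean over samples of the squared l2 norm of the residual image."""
    if len(predictions) == 0 or len(predictions) != len(truths):
        raise ValueError("predictions and truths must be non-empty, equal-length lists")
    total = 0.0
    for p, t in zip(predictions, truths):
        p, t = np.asarray(p, dtype=float), np.asarray(t, dtype=float)
        if p.shape != t.shape:
            raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
        total += float(np.sum((p - t) ** 2))
    return total / len(predictions)


class _Adam:
    """Adam over a list of numpy parameter arrays (scalars included)."""

    def __init__(self, shapes: list[tuple], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> list[np.ndarray]:
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            g = np.asarray(g, dtype=float)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def _stack_cases(
    cases: Sequence[PairedCase], norm: Normalization, dtype
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    for c in cases:
        if c.post is None:
            raise ValueError(f"case {c.case_id} has no post image")
    pre = np.stack([c.pre.values for c in cases]).astype(dtype) / norm.suv_scale
    dose = np.stack([c.dose.values for c in cases]).astype(dtype) / norm.dose_scale
    post = np.stack([c.post.values for c in cases]).astype(dtype) / norm.suv_scale
    return pre, dose, post


def _forward_batch(
    net: ResponseNet,
    alpha: float,
    beta: float,
    pre: np.ndarray,
    dose: np.ndarray,
    params: ReactionDiffusionParams,
    train: bool,
):
    """Unroll the Euler update on a batch; returns final state and step caches."""
    h = params.h
    U = pre
    steps = []
    for n in range(params.n_steps):
        lap = discrete_laplacian(U, params.boundary)
        psi = dose * U
        r, cache = net.forward(psi[..., None].astype(net.dtype), train=train, step=n)
        r = r[..., 0].astype(U.dtype)
        U_next = U + h * (alpha * lap + beta * U) + h * r
        steps.append((U, lap, cache))
        U = U_next
    return U, steps


def _backward_batch(
    net: ResponseNet,
    alpha: float,
    beta: float,
    dose: np.ndarray,
    dU: np.ndarray,
    steps: list,
    params: ReactionDiffusionParams,
) -> tuple[float, float]:
    """Backpropagate dL/dU_final through the unrolled steps.

    Network parameter gradients accumulate inside ``net``; returns the
    gradients with respect to alpha and beta.
    """
    h = params.h
    d_alpha = 0.0
    d_beta = 0.0
    g = dU
    for U, lap, cache in reversed(steps):
        d_alpha += float(np.sum(g * lap)) * h
        d_beta += float(np.sum(g * U)) * h
        dpsi = net.backward((h * g)[..., None].astype(net.dtype), cache)[..., 0].astype(g.dtype)
        g = (
            g
            + h * (alpha * discrete_laplacian_adjoint(g, params.boundary) + beta * g)
            + dpsi * dose
        )
    return d_alpha, d_beta


def _epoch_loss(
    net: ResponseNet,
    alpha: float,
    beta: float,
    pre: np.ndarray,
    dose: np.ndarray,
    post: np.ndarray,
    params: ReactionDiffusionParams,
    batch_size: int,
) -> float:
    """Inference-mode loss over a dataset, batched to bound memory."""
    total = 0.0
    for i in range(0, len(pre), batch_size):
        U, _ = _forward_batch(
            net, alpha, beta, pre[i : i + batch_size], dose[i : i + batch_size],
            params, train=False,
        )
        total += float(np.sum((U - post[i : i + batch_size]) ** 2))
    return total / len(pre)


def train(
    cases: Sequence[PairedCase],
    val_cases: Sequence[PairedCase],
    net_cfg: ResponseNetConfig | None = None,
    pde: ReactionDiffusionParams | None = None,
    tcfg: TrainingConfig | None = None,
    normalization: Normalization | None = None,
    dtype=np.float32,
) -> TrainedModel:
    """Fit theta, alpha, beta on paired (pre, dose, post) cases.

    Returns the model of the best validation epoch, with the per-epoch
    train/validation losses in ``training_history``.
    """
    net_cfg = net_cfg or ResponseNetConfig()
    pde = pde or ReactionDiffusionParams()
    tcfg = tcfg or TrainingConfig()
    norm = normalization or Normalization()
    if len(val_cases) == 0:
        raise ValueError("val_cases must be non-empty")

    pre, dose, post = _stack_cases(cases, norm, dtype)
    vpre, vdose, vpost = _stack_cases(val_cases, norm, dtype)

    net = ResponseNet(net_cfg, seed=tcfg.seed, dtype=dtype)
    a_raw = softplus_inverse(tcfg.alpha_init)
    beta = tcfg.beta_init

    # the two PDE scalars get their own Adam group: the softplus transform
    # scales alpha's gradient by sigmoid(alpha_raw) (~1e-2 at the default
    # init), so sharing the network learning rate would let the operator
    # converge long before the coefficients have moved
    opt_net = _Adam([p.shape for _, p in _param_arrays(net)], tcfg.learning_rate)
    opt_coef = _Adam([(), ()], tcfg.coefficient_learning_rate)
    rng = np.random.default_rng(tcfg.seed)

    best_val = np.inf
    best_state = (net.state_dict(), a_raw, beta)
    best_epoch = -1
    last_decay = -1
    history: list[dict] = []

    n = len(pre)
    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(n)
        train_total = 0.0
        for i in range(0, n, tcfg.batch_size):
            idx = order[i : i + tcfg.batch_size]
            b_pre, b_dose, b_post = pre[idx], dose[idx], post[idx]
            alpha = softplus(a_raw)

            net.zero_grad()
            U, steps = _forward_batch(net, alpha, beta, b_pre, b_dose, pde, train=True)
            resid = U - b_post
            loss = float(np.sum(resid**2)) / len(idx)
            if not np.isfinite(loss):
                raise FloatingPointError(f"training loss became non-finite at epoch {epoch}")
            train_total += loss * len(idx)

            dU = (2.0 / len(idx)) * resid
            d_alpha, d_beta = _backward_batch(net, alpha, beta, b_dose, dU, steps, pde)
            d_a_raw = d_alpha * sigmoid(a_raw)

            new_coef = opt_coef.step(
                [np.float64(a_raw), np.float64(beta)],
                [np.float64(d_a_raw), np.float64(d_beta)],
            )
            a_raw, beta = float(new_coef[0]), float(new_coef[1])
            updated = opt_net.step(
                [p for _, p in _param_arrays(net)], [g for _, g in _grad_arrays(net)]
            )
            for (layer, name), new in zip(_param_names(net), updated):
                layer.params[name] = new.astype(dtype)

        alpha = softplus(a_raw)
        train_loss = train_total / n
        val_loss = _epoch_loss(net, alpha, beta, vpre, vdose, vpost, pde, tcfg.batch_size)
        history.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "val_loss": val_loss,
                "alpha": alpha,
                "beta": beta,
                "lr": opt_net.lr,
            }
        )

        if val_loss < best_val:
            best_val = val_loss
            best_state = (net.state_dict(), a_raw, beta)
            best_epoch = epoch
        elif epoch - best_epoch >= tcfg.patience:
            break
        # halve both learning rates when validation stalls: damps the late
        # random-walk of the two coefficients around their optimum
        if epoch - max(best_epoch, last_decay) >= tcfg.lr_plateau_patience:
            opt_net.lr *= tcfg.lr_plateau_factor
            opt_coef.lr *= tcfg.lr_plateau_factor
            last_decay = epoch

    net.load_state_dict(best_state[0])
    model = TrainedModel(
        net=net,
        alpha_raw=best_state[1],
        beta=best_state[2],
        pde=pde,
        normalization=norm,
        training_history=history,
    )
    return model


def _param_names(net: ResponseNet) -> list[tuple]:
    return net.parameters()


def _param_arrays(net: ResponseNet) -> list[tuple[tuple, np.ndarray]]:
    return [((l, n), l.params[n]) for l, n in net.parameters()]


def _grad_arrays(net: ResponseNet) -> list[tuple[tuple, np.ndarray]]:
    return [((l, n), l.grads[n]) for l, n in net.parameters()]
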