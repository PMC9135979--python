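"""Encoder-decoder convolutional network for the dose-response operator.

The network maps the coupling field psi = D o U (one channel) to a response
field of the same shape. At defaults it has exactly seven convolutional
layers arranged as a small U-Net with one resolution level:

    [3x3 conv(16) + BN + ReLU] x2            (contracting, full resolution)
    2x2 max-pool, channels doubled to 32
    [3x3 conv(32) + BN + ReLU] x2            (bottleneck)
    nearest up-sample x2, optional skip concatenation
    [3x3 conv(16) + BN + ReLU] x2            (expanding)
    1x1 conv 16 -> 1                         (zero-initialized)

The zero-initialized final layer makes a freshly built network the exact
zero operator, so an untrained model runs pure diffusion-proliferation
dynamics — a stable, interpretable starting point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import BatchNorm2d, Conv2d, Layer, MaxPool2d, ReLU, UpsampleNearest2d


@dataclass(frozen=True)
class ResponseNetConfig:
    """Architecture hyper-parameters of the response network."""

    base_channels: int = 16
    kernel_size: int = 3
    pool_size: int = 2
    levels: int = 2
    use_skip_connection: bool = True
    final_kernel: int = 1

    def __post_init__(self) -> None:
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.levels != 2:
            raise ValueError("only the two-level (one down-sampling) layout is supported")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")

    @property
    def conv_layer_count(self) -> int:
        # 2 contracting + 2 bottleneck + 2 expanding + final 1x1
        return 7


class ResponseNet:
    """The learnable response operator N_F(psi; theta)."""

    def __init__(self, config: ResponseNetConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c = config.base_channels
        k = config.kernel_size

        def conv(i, o, ks=k, zero=False):
            return Conv2d(i, o, ks, rng, zero_init=zero, dtype=dtype)

        self.enc = [conv(1, c), BatchNorm2d(c, dtype=dtype), ReLU(),
                    conv(c, c), BatchNorm2d(c, dtype=dtype), ReLU()]
        self.pool = MaxPool2d(config.pool_size)
        self.mid = [conv(c, 2 * c), BatchNorm2d(2 * c, dtype=dtype), ReLU(),
                    conv(2 * c, 2 * c), BatchNorm2d(2 * c, dtype=dtype), ReLU()]
        self.up = UpsampleNearest2d(config.pool_size)
        dec_in = 2 * c + (c if config.use_skip_connection else 0)
        self.dec = [conv(dec_in, c), BatchNorm2d(c, dtype=dtype), ReLU(),
                    conv(c, c), BatchNorm2d(c, dtype=dtype), ReLU()]
        self.final = conv(c, 1, ks=config.final_kernel, zero=True)

    # -- bookkeeping --------------------------------------------------------

    def layers(self) -> list[Layer]:
        return [*self.enc, self.pool, *self.mid, self.up, *self.dec, self.final]

    @property
    def conv_layer_count(self) -> int:
        return sum(1 for l in self.layers() if isinstance(l, Conv2d))

    def zero_grad(self) -> None:
        for l in self.layers():
            l.zero_grad()

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(l, name) for l in self.layers() for name in l.params]

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, l in enumerate(self.layers()):
            for name, p in l.params.items():
                state[f"layer{i}.{name}"] = p.copy()
            if isinstance(l, BatchNorm2d):
                for step, m in l.running_mean.items():
                    state[f"layer{i}.running_mean.{step}"] = m.copy()
                    state[f"layer{i}.running_var.{step}"] = l.running_var[step].copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self.layers()):
            for name in l.params:
                l.params[name] = state[f"layer{i}.{name}"].astype(self.dtype).copy()
            if isinstance(l, BatchNorm2d):
                l.running_mean, l.running_var = {}, {}
                prefix = f"layer{i}.running_mean."
                for key in state:
                    if key.startswith(prefix):
                        step = int(key[len(prefix):])
                        l.running_mean[step] = state[key].astype(self.dtype).copy()
                        l.running_var[step] = state[
                            f"layer{i}.running_var.{step}"
                        ].astype(self.dtype).copy()

    # -- forward / backward -------------------------------------------------

    def _pad_to_pool(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        s = self.config.pool_size
        H, W = x.shape[1], x.shape[2]
        ph, pw = (-H) % s, (-W) % s
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="edge")
        return x, (ph, pw)

    def forward(self, x: np.ndarray, train: bool = True, step: int = 0):
        """Map (B, H, W, 1) -> (B, H, W, 1); returns (output, cache).

        ``step`` selects the batch-norm statistics of the unrolled time step
        being evaluated. Inputs whose spatial size is not divisible by the
        pool size are edge-padded on entry and cropped on exit.
        """

        def run(layer, x):
            if isinstance(layer, BatchNorm2d):
                return layer.forward(x, train, step=step)
            return layer.forward(x, train)

        x = np.asarray(x, dtype=self.dtype)
        H0, W0 = x.shape[1], x.shape[2]
        x, pad = self._pad_to_pool(x)
        caches: list = [pad, (H0, W0)]
        for l in self.enc:
            x, c = run(l, x)
            caches.append(c)
        skip = x
        x, c = self.pool.forward(x, train)
        caches.append(c)
        for l in self.mid:
            x, c = run(l, x)
            caches.append(c)
        x, c = self.up.forward(x, train)
        caches.append(c)
        if self.config.use_skip_connection:
            x = np.concatenate([skip, x], axis=3)
        for l in self.dec:
            x, c = run(l, x)
            caches.append(c)
        x, c = self.final.forward(x, train)
        caches.append(c)
        if pad != (0, 0):
            x = x[:, :H0, :W0, :]
        return x, caches

    def backward(self, dy: np.ndarray, caches: list) -> np.ndarray:
        """Backpropagate; accumulates parameter gradients, returns d(input)."""
        dy = np.asarray(dy, dtype=self.dtype)
        it = iter(caches)
        pad = next(it)
        H0, W0 = next(it)
        cs = list(it)
        if pad != (0, 0):
            dy = np.pad(dy, ((0, 0), (0, pad[0]), (0, pad[1]), (0, 0)))
        i = len(cs) - 1
        dy = self.final.backward(dy, cs[i]); i -= 1
        for l in reversed(self.dec):
            dy = l.backward(dy, cs[i]); i -= 1
        if self.config.use_skip_connection:
            c = self.config.base_channels
            dskip, dy = dy[..., :c], dy[..., c:]
        else:
            dskip = None
        dy = self.up.backward(dy, cs[i]); i -= 1
        for l in reversed(self.mid):
            dy = l.backward(dy, cs[i]); i -= 1
        dy = self.pool.backward(dy, cs[i]); i -= 1
        if dskip is not None:
            dy = dy + dskip
        for l in reversed(self.enc):
            dy = l.backward(dy, cs[i]); i -= 1
        if pad != (0, 0):
            # adjoint of the entry edge-pad: fold replicated rows/cols back
            dx = dy[:, :H0, :W0, :].copy()
            if pad[0]:
                dx[:, H0 - 1, :, :] += dy[:, H0:, :W0, :].sum(axis=1)
            if pad[1]:
                dx[:, :, W0 - 1, :] += dy[:, :H0, W0:, :].sum(axis=2)
            if pad[0] and pad[1]:
                dx[:, H0 - 1, W0 - 1, :] += dy[:, H0:, W0:, :].sum(axis=(1, 2))
            dy = dx
        return np.ascontiguousarray(dy)

    # -- inference on a single 2D field -------------------------------------

    def predict_field(self, psi: np.ndarray, step: int = 0) -> np.ndarray:
        """Apply the network in inference mode to one 2D field."""
        y, _ = self.forward(psi[None, :, :, None], train=False, step=step)
        return y[0, :, :, 0].astype(float)
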