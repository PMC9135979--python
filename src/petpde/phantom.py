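"""Seeded synthetic phantom cases: pre-radiation SUV, dose map, simulated post.

Each case emulates one axial slice of a head-and-neck FDG-PET study with a
planned dose distribution: an elliptical body on zero background, background
uptake near SUV 1, one to a few Gaussian hotspots with clear edges, and a
smooth dose composite rescaled to the prescribed maximum. The post-radiation
image is produced by simulating the reaction-diffusion model forward with a
known analytic response operator at a finer time discretization than the
predictive model unrolls (40 steps vs 4), so that learning from these cases
is not an inverse crime, plus additive noise inside the body.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .grid import Grid2D, PairedCase, Quantity, ScalarField2D
from .pde import (
    ReactionDiffusionParams,
    ResponseOperator,
    linear_kill_response,
    saturating_kill_response,
    simulate_forward,
)


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters; defaults are the study conditions of the package.

    Ranges are (low, high) and sampled uniformly per case. Spatial scales are
    in mm; SUV and Gy as labelled. ``true_alpha``/``true_beta`` and the
    response define the ground-truth dynamics that produce the post image.
    """

    grid: Grid2D = Grid2D(64, 64, 2.5, 2.5)
    n_hotspots: tuple[int, int] = (1, 3)
    hotspot_peak_suv: tuple[float, float] = (3.0, 8.0)
    hotspot_sigma_mm: tuple[float, float] = (4.0, 10.0)
    background_suv: float = 1.0
    background_noise_sd: float = 0.05
    body_ellipse_axes_frac: tuple[float, float] = (0.8, 0.65)
    dose_max_gy: float = 20.0
    dose_sigma_mm: float = 15.0
    true_alpha: float = 0.05
    true_beta: float = -0.1
    response: Literal["linear", "saturating"] = "linear"
    gamma: float = 0.4
    psi_half: float = 4.0
    post_noise_sd: float = 0.05
    n_steps_sim: int = 40
    total_time: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hotspots", "hotspot_peak_suv", "hotspot_sigma_mm"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range must have low <= high")
        if self.background_noise_sd < 0 or self.post_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.dose_max_gy <= 0:
            raise ValueError("dose_max_gy must be positive")

    def response_operator(self) -> ResponseOperator:
        if self.response == "linear":
            return linear_kill_response(self.gamma)
        if self.response == "saturating":
            return saturating_kill_response(self.gamma, self.psi_half)
        raise ValueError(f"unknown response kind {self.response!r}")


def _ellipse_mask(grid: Grid2D, axes_frac: tuple[float, float]) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    cr, ccen = (grid.n_rows - 1) / 2.0, (grid.n_cols - 1) / 2.0
    ar = axes_frac[0] * grid.n_rows / 2.0
    ac = axes_frac[1] * grid.n_cols / 2.0
    return ((rr - cr) / ar) ** 2 + ((cc - ccen) / ac) ** 2 <= 1.0


def _gaussian_blob(grid: Grid2D, center_px: tuple[float, float], sigma_mm: float) -> np.ndarray:
    rows_mm, cols_mm = grid.pixel_centers_mm()
    dr = rows_mm - center_px[0] * grid.spacing_row_mm
    dc = cols_mm - center_px[1] * grid.spacing_col_mm
    r2 = dr[:, None] ** 2 + dc[None, :] ** 2
    return np.exp(-r2 / (2.0 * sigma_mm**2))


def generate_case(spec: PhantomSpec, case_seed: int) -> PairedCase:
    """One deterministic phantom case for (spec.seed, case_seed)."""
    rng = np.random.default_rng([spec.seed, case_seed])
    grid = spec.grid
    body = _ellipse_mask(grid, spec.body_ellipse_axes_frac)

    n_hot = int(rng.integers(spec.n_hotspots[0], spec.n_hotspots[1] + 1))
    centers = []
    for _ in range(n_hot):
        for _attempt in range(100):
            r = rng.uniform(0, grid.n_rows - 1)
            c = rng.uniform(0, grid.n_cols - 1)
            if body[int(round(r)), int(round(c))]:
                centers.append((r, c))
                break
        else:
            raise RuntimeError("could not place a hotspot inside the body after 100 tries")

    pre_clean = np.where(body, spec.background_suv, 0.0)
    for r, c in centers:
        peak = rng.uniform(*spec.hotspot_peak_suv)
        sigma = rng.uniform(*spec.hotspot_sigma_mm)
        pre_clean = pre_clean + peak * _gaussian_blob(grid, (r, c), sigma) * body
    pre_vals = pre_clean + rng.normal(0.0, spec.background_noise_sd, grid.shape) * body
    pre_vals = np.maximum(pre_vals, 0.0) * body

    # dose: broad Gaussians at the hotspot centers, feathered toward ~20%
    # outside the body margin, rescaled to the prescribed maximum
    dose_raw = np.zeros(grid.shape)
    for r, c in centers:
        dose_raw += _gaussian_blob(grid, (r, c), spec.dose_sigma_mm)
    sigma_px = 5.0 / max(grid.spacing_row_mm, grid.spacing_col_mm)
    feather = ndimage.gaussian_filter(body.astype(float), sigma_px)
    dose_vals = dose_raw * (0.2 + 0.8 * feather)
    dose_vals *= spec.dose_max_gy / dose_vals.max()

    params = ReactionDiffusionParams(
        alpha=spec.true_alpha,
        beta=spec.true_beta,
        n_steps=spec.n_steps_sim,
        total_time=spec.total_time,
    )
    pre_field = ScalarField2D(grid, pre_clean, Quantity.SUV)
    dose_field = ScalarField2D(grid, dose_vals, Quantity.DOSE_GY)
    traj = simulate_forward(
        pre_field, dose_field, params, spec.response_operator(), clip_negative=True
    )
    post_clean = traj.final.values * body
    post_vals = post_clean + rng.normal(0.0, spec.post_noise_sd, grid.shape) * body
    post_vals = np.maximum(post_vals, 0.0) * body

    ground_truth = {
        "alpha": spec.true_alpha,
        "beta": spec.true_beta,
        "response": spec.response,
        "gamma": spec.gamma,
        "psi_half": spec.psi_half if spec.response == "saturating" else None,
        "n_hotspots": n_hot,
        "hotspot_centers_px": [[float(r), float(c)] for r, c in centers],
        "n_steps_sim": spec.n_steps_sim,
    }
    return PairedCase(
        pre=ScalarField2D(grid, pre_vals, Quantity.SUV),
        dose=dose_field,
        post=ScalarField2D(grid, post_vals, Quantity.SUV),
        post_clean=ScalarField2D(grid, post_clean, Quantity.SUV),
        body_mask=body,
        case_id=f"phantom_{case_seed:04d}",
        ground_truth=ground_truth,
    )


@dataclass
class PhantomDataset:
    train: list[PairedCase] = field(default_factory=list)
    val: list[PairedCase] = field(default_factory=list)
    test: list[PairedCase] = field(default_factory=list)

    @property
    def all_cases(self) -> list[PairedCase]:
        return self.train + self.val + self.test


def generate_dataset(
    spec: PhantomSpec,
    n_cases: int,
    split: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> PhantomDataset:
    """Generate n_cases phantoms and split them case-wise train/val/test.

    Split sizes are the rounded fractions; membership is deterministic given
    ``spec.seed``.
    """
    if n_cases < 5:
        raise ValueError("need at least 5 cases to split")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_train = int(round(split[0] * n_cases))
    n_val = int(round(split[1] * n_cases))
    n_test = n_cases - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"empty split: sizes ({n_train}, {n_val}, {n_test})")

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n_cases)
    cases = [generate_case(spec, i) for i in range(n_cases)]
    ds = PhantomDataset(
        train=[cases[i] for i in order[:n_train]],
        val=[cases[i] for i in order[n_train : n_train + n_val]],
        test=[cases[i] for i in order[n_train + n_val :]],
    )
    return ds


def split_assignments(spec: PhantomSpec, n_cases: int,
                      split: tuple[float, float, float] = (0.6, 0.2, 0.2)) -> dict[str, str]:
    """case_id -> split-name mapping, identical to :func:`generate_dataset`."""
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_train = int(round(split[0] * n_cases))
    n_val = int(round(split[1] * n_cases))
    if min(n_train, n_val, n_cases - n_train - n_val) < 1:
        raise ValueError("every split must receive at least one case")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n_cases)
    out = {}
    for pos, i in enumerate(order):
        name = "train" if pos < n_train else ("val" if pos < n_train + n_val else "test")
        out[f"phantom_{i:04d}"] = name
    return out
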