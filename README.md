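# petpde

Biologically guided prediction of post-radiotherapy FDG-PET images.

Radiation oncologists would like to know, at planning time, how a tumor's
metabolic image will look partway through radiotherapy: that forecast can
drive adaptive re-planning. `petpde` implements a physics-informed approach
to this image-outcome-prediction problem for 2D axial PET slices: instead of
a black-box image-to-image network, the predictor *is* a discretized
biological model whose unknown part is learned.

## The model

The standardized-uptake-value field U evolves by a dose-coupled
reaction–diffusion equation,

    U_t = α ΔU + β U + F(D ∘ U),

with diffusion coefficient α > 0, proliferation rate β, planned dose map D,
and an unknown response operator F acting on the dose–uptake product
ψ = D ∘ U. Forward-Euler discretization with a nine-point Laplacian stencil
gives the unrolled update

    U^{n+1} = U^n + h·(α Δ₉U^n + β U^n) + h·F(D ∘ U^n),   h = T/Nt,

run for Nt = 4 steps from the pre-radiation image to the predicted
post-radiation image. F is a seven-layer encoder–decoder convolutional
network trained jointly with the two scalars α, β by minimizing the l2 loss
against ground-truth post images (Adam, batches of 10, early stopping on
validation loss). Because each term is accumulated during the unroll, every
prediction decomposes exactly into three interpretable effect maps —
diffusion, proliferation and dose response.

The package ships:

- the discretized PDE core and analytic response operators (`petpde.pde`),
- the unrolled two-branch model, a self-contained numpy network engine with
  verified gradients, training and checkpointing (`petpde.nn`),
- a seeded phantom generator that simulates ground-truth dynamics at a finer
  time discretization than the model unrolls (`petpde.phantom`),
- the evaluation protocol: Otsu high-uptake segmentation, SUV means, Dice,
  and multi-criteria 2D gamma analysis (`petpde.evaluation`),
- NIfTI ingestion, bilinear resampling, SUVmax slice filtering
  (`petpde.grid`), and a thin `petpde` command-line interface.

## Worked example

```sh
python examples/03_train_and_recover.py
```

trains on 30 quarter-resolution phantoms generated with known dynamics
(α = 0.05, β = −0.1, linear kill γ = 0.4) and prints:

```
phantoms: 18 train / 6 val / 6 test
true dynamics: alpha=0.05, beta=-0.1, linear kill gamma=0.4
epochs run: 30; validation loss 45.06 -> 0.400
recovered alpha = 0.0153  beta = -0.1875
test case phantom_0022: mean abs SUV error inside body = 0.162
breakdown means inside body (SUV change attributed to each effect):
  diffusion     -0.0042
  proliferation -0.2144
  dose response -1.5876
```

The validation loss collapses as the network learns the kill operator; the
dose-response map carries most of the SUV change, as it should when hotspots
receive up to 20 Gy. At this deliberately tiny scale the two scalar
coefficients are only loosely determined — the full-scale experiment in
`scripts/acceptance.py` (150 cases at 64×64) pins them down. The other
examples demonstrate phantom generation (`01`), the forward solver and its
conservation/closed-form checks (`02`), and the evaluation protocol (`04`).

The same workflow is available from the shell:

```sh
petpde simulate-phantoms --n-cases 150 --seed 0 --out data/
petpde train    --data data/ --out run/
petpde predict  --checkpoint run/checkpoint.npz --data data/ --out pred/
petpde evaluate --data data/ --predictions pred/ --out report/
```

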