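# riciantv

Variational removal of Rician noise from magnitude MR images.

Magnitude MR intensities follow a Rician distribution — the modulus of
complex data with Gaussian channel noise — which is signal-dependent and
biased, so Gaussian denoisers are mis-specified for MRI.  `riciantv`
implements a spatially variant high-order variational model (SVHOVM) for
this problem: the Rician MAP data fidelity, made strictly convex by a
square-root quadratic term, combined with an **edge-adaptive total
variation** regularizer and a **bounded Hessian** term,

    min_u  ‖u‖²/(2σ²) − ⟨log I₀(uf/σ²), 1⟩ + ‖√u − √f‖²/σ
           + ‖α(·)∇u‖₁ + β‖∇²u‖₁,
    α(x) = α₀ / √(1 + (|∇(G_ω∗x)|/κ)²)

The per-pixel weight α smooths strongly in flat regions and backs off at
edges; the second-order β-term suppresses the staircase plateaus plain TV
creates in smoothly varying regions.  The problem is solved by a split
Bregman algorithm: closed-form isotropic shrinkage for the gradient and
Hessian splits, a diagonal quasi-Newton image update, and dual-variable
ascent, with the weight map refreshed each outer iteration from the
current restored image.

The package is for researchers in MR image analysis and variational
imaging: it ships the solver, a seeded Rician noise simulator with stable
Bessel utilities, three published first-order baseline models (GTV, CZ,
Yuan) on the same solver scaffold for fair comparison, PSNR/SSIM metrics,
a synthetic phantom suite with exact ground truth, and a CLI.

## Worked example

```python
import riciantv as rtv

spec = dict(rtv.standard_suite())["flat+disks-128"]
clean, edge_mask, ramp_mask = rtv.make_phantom(spec)
noisy = rtv.add_rician_noise(clean, rtv.NoiseModel(sigma=15.0, seed=1))

params = rtv.SolverParams(
    sigma=15.0,
    weight=rtv.WeightParams(alpha0=160.0, kappa=0.8, omega=1.0),
    beta=2.0,
    k_max=200,
)
result = rtv.denoise(noisy, params)

print(f"noisy:    PSNR {rtv.psnr(noisy, clean):.2f} dB  SSIM {rtv.ssim(noisy, clean):.4f}")
print(f"denoised: PSNR {rtv.psnr(result.u_hat, clean):.2f} dB  SSIM {rtv.ssim(result.u_hat, clean):.4f}")
print(f"weight map: mean on edges {result.alpha_final[edge_mask].mean():.2f}, "
      f"off edges {result.alpha_final[~edge_mask].mean():.2f}")
```

Output:

```
noisy:    PSNR 25.07 dB  SSIM 0.9700
denoised: PSNR 32.50 dB  SSIM 0.9944
weight map: mean on edges 8.92, off edges 138.07
```

The restored image gains about 7.4 dB over the σ = 15 corrupted input,
and the final weight map shows the spatial adaptivity at work: TV
smoothing is ~15× weaker on object edges than in flat regions, which is
what preserves boundaries while noise is removed.  `tune_params` runs an
alternating PSNR-maximizing search over (α₀, β) grids when a clean
reference is available; see `docs/methods.md` for parameter guidance and
the full model description.

## Command line

```bash
riciantv phantom --out-dir phantoms
riciantv add-noise phantoms/flat+disks-128.png noisy.png --sigma 15 --seed 1
riciantv denoise noisy.png restored.png --model svhovm --sigma 15 \
    --alpha0 160 --beta 2 --iters 200 --ref phantoms/flat+disks-128.png
riciantv evaluate restored.png --ref phantoms/flat+disks-128.png
riciantv bench --models svhovm,gtv,cz,yuan --sigmas 5,15,25 --out bench.csv
```

`denoise` accepts PNG, 8/16-bit TIFF, and NIfTI (slice-wise) inputs and
writes a JSON sidecar with the full effective configuration, iteration
count, energy trace and metrics.  `--model` selects `svhovm` (default),
`gtv`, `cz` or `yuan`.

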