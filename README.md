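# mwtomo — adaptive subspace TwIST microwave tomography in 2D

Microwave tomography images the interior of an object — most prominently
the breast — by surrounding it with a ring of antennas, measuring the
scattered microwave field for many transmitter/receiver pairs, and solving
the nonlinear, ill-posed inverse scattering problem for the dielectric
profile.  `mwtomo` is a complete, self-contained 2D (TMz) pipeline for
studying one family of reconstruction algorithms: the distorted Born
iterative method (DBIM) enhanced with **subspace-extracted deterministic
contrast sources** and **adaptive selection of the subspace rank**, with a
two-step iterative shrinkage/thresholding (TwIST) inner solver under
Tikhonov regularization.

The core update works on the linearized model

    E_sca  ≈  G_S·χ·E_bac + G_bS·Δχ·E_tot,
    E_tot  =  E_bac + G_bD·C,
    C      =  Σ_{i≤L} (u_i*·r / s_i) v_i,     G_bS = Σ_i u_i s_i v_i*,

where `G_bS`, `G_bD` are the Green operators of the current inhomogeneous
background, `r` is the data residual, and the truncation rank `L` controls
how much of the receiver-space range of `G_bS` feeds the induced-current
estimate.  `L = 0` recovers plain DBIM; large `L` divides by small singular
values and amplifies noise.  Because the best `L` depends on the (unknown)
noise level, every outer iteration evaluates a small candidate set
(`L = 5, 10, 15, 20`) on a half-resolution copy of the problem and keeps
the rank with the smallest regularized cost

    F(Δχ) = ‖E_sca − G_S·χ·E_bac − G_bS·Δχ·E_tot‖² + γ‖Δχ‖².

The package contains the frequency-domain method-of-moments forward
simulator (FFT-accelerated volume integral equation with an analytic
Richmond self term), benchmark phantoms (the "Austria" profile and a seeded
synthetic breast generator with a linear permittivity→conductivity tissue
model), the inverse solver stack, error metrics, experiment presets and a
small CLI.  See `docs/methods.md` for the scientific details and design
choices.

## Worked example

Reconstruct the Austria profile (two ε_r = 2 disks plus an annulus in free
space, 2 m domain, 400 MHz, 10 transmitters / 30 receivers at 1.5 m) from
data simulated on a two-times-finer grid at 10 dB SNR:

```python
from mwtomo import forward as fwd
from mwtomo.metrics_io import austria_scene, austria_born_init, run_austria

truth, fine, array = austria_scene()          # 64x64 inverse grid
meas = fwd.simulate_experiment(truth, array, snr_db=10.0, seed=1,
                               fine_factor=2, fine_map=fine)
init = austria_born_init(meas)                # linearized starting guess

res, _, _ = run_austria(1, 10.0, "adaptive", meas=meas, init_map=init)
print(f"xi_pixel: {res.xi_initial:.2f}% -> {res.final_xi_pixel:.2f}% "
      f"in {len(res.history)} outer iterations (converged={res.converged})")
```

which prints

```
xi_pixel: 7.49% -> 2.44% in 24 outer iterations (converged=True)
```

`xi_pixel` is the mean *squared* relative permittivity error in percent, so
2.44% corresponds to a ~16% RMS per-pixel deviation at 10 dB SNR.  Running
the same data with `policy="fixed:30"` (all 30 singular values) ends far
higher — the noise-amplification failure mode the adaptive rank
selection exists to avoid — and at 0 dB SNR the fixed `L = 30` run fails to
improve on its initial guess at all.

The same machinery runs from the shell:

```bash
mwtomo phantom make --kind austria --grid 64 --out austria.txt
mwtomo preset run --name austria_snr_sweep --seeds 1..3 --out results/
```

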