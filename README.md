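# rpinverse

Forward and inverse modelling of photoreceptor degeneration in retinitis
pigmentosa (RP) under the trophic factor hypothesis.

RP destroys rod photoreceptors first (they express the mutant gene) and
cones second.  A leading explanation for the secondary cone loss is
depletion of rod-derived cone viability factor (RdCVF), a diffusible
protein produced by rods and required by cones.  This package implements
a 1D reaction–diffusion model of that mechanism on the retinal meridian
between the fovea (θ = 0) and the ora serrata (θ = 1; Θ = 1.33 rad):

    ∂f/∂t   = D_f [f_θθ + Θ cot(Θθ) f_θ] + α p_r − β f p_c − η f
    ∂p_r/∂t = −φ_r(θ) p_r
    ∂p_c/∂t = −p_c [1 − H(f − f_crit(θ))]

where f is the trophic factor concentration, p_r and p_c the rod and cone
densities, φ_r(θ) the mutation-induced rod degeneration rate, and
f_crit(θ) the TF threshold below which cones die.  Cone degeneration at a
location is timed by the first crossing of p_c/p̃_c = 0.99, defining the
degeneration profile t_degen(θ).

The package then solves the **inverse problem**: given a target t_degen(θ)
shaped like a clinically observed pattern of visual-field loss (peripheral
restriction, para-foveal ring, mid-peripheral onset), recover the φ_r(θ)
or f_crit(θ) profile that produces it — both by closed-form
quasi-steady-state asymptotics, e.g.

    φ_r_inv(θ) = [ln(α B₃ θ / (β B₂ f_crit)) − (b₃ − b₂)θ] / t_degen(θ)

and by simulation-in-the-loop derivative-free optimization (Nelder–Mead /
coordinate pattern search) in the region near the fovea where the
asymptotics break down.

Intended users: modellers of retinal degeneration and, more broadly,
anyone studying profile-recovery inverse problems for reaction–diffusion
systems on spherical domains.

## Worked example

```python
import numpy as np
import rpinverse as rp

params = rp.make_parameters(1)           # Scaling 1: alpha=7.01e4, beta=1.79e6

# Healthy steady-state trophic factor (4001-node finite-difference solve)
f_init = rp.steady_state_tf(params.rod_profile, params.cone_profile,
                            params, n_mesh=4001)
print(f"min f_init = {f_init.values.min():.3e} (threshold 3e-05)")

# A mid-peripheral-onset target degeneration pattern (Pattern 3, cubic)
target = rp.make_target("3", "cubic")
print(f"target t_degen(0)   = {target(0.0):.1f}  (~{rp.time_to_years(target(0.0)):.1f} yr)")
print(f"target t_degen(0.4) = {target(0.4):.1f}  (~{rp.time_to_years(target(0.4)):.1f} yr)")

# Closed-form rod-degeneration-rate profile that reproduces it
theta = np.linspace(0.05, 1.0, 20)
phi_inv = rp.phi_r_inverse(theta, target, 3e-5, params)
print(f"phi_r_inv range: {phi_inv.min():.4f} .. {phi_inv.max():.4f}")
back = rp.t_degen_analytic(theta, phi_inv, 3e-5, params)
print(f"round-trip max error: {np.max(np.abs(back - target(theta))):.2e}")
```

prints

```
min f_init = 1.059e-04 (threshold 3e-05)
target t_degen(0)   = 200.0  (~22.1 yr)
target t_degen(0.4) = 100.0  (~11.0 yr)
phi_r_inv range: 0.0482 .. 0.1031
round-trip max error: 1.42e-14
```

Reading the numbers: the healthy steady-state TF concentration stays above
the cone-survival threshold everywhere (minimum 1.06×10⁻⁴ at the fovea),
so without rod loss no cones die.  The chosen target has cones surviving
22 years at the fovea but only 11 years at eccentricity 0.4.  To produce
that pattern, rods must degenerate fastest (rate ≈ 0.10) where cone loss
is earliest and slowest (≈ 0.05) toward the fovea; composing the forward
asymptotic map with the recovered profile returns the target to machine
precision.

For the simulation-corrected inverse near the fovea:

```python
result = rp.numerical_inverse(target, "phi_r", params,
                              rp.InverseConfig(n_mesh=26, scaling=1))
```

which stitches optimized node values inside the failure region with the
analytic inverse outside it (`result.to_frame()` tabulates profile,
region membership, and per-node residuals).

A CLI mirrors the library:

```sh
rpinverse steady-state --scaling 1 --n-mesh 4001
rpinverse target --pattern 1B --subpattern linear
rpinverse invert-analytic --pattern 3 --subpattern cubic --which phi_r
rpinverse invert --pattern uniform --which f_crit --n-mesh 26
rpinverse reproduce forward-contours --scaling 2 --n-mesh 401
```

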