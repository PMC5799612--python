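"""Position-dependent diffusivity from restrained windows.

Simulates a few umbrella windows across a landscape whose diffusivity
drops 10-fold inside |z| < 15 Å, then recovers D(z) per window with the
restrained-coordinate estimator: D = ⟨δz²⟩/τ, with τ from the Laplace
transform of the position autocorrelation function extrapolated to
s → 0 by an a/(s+b) fit.
"""

import numpy as np

import memperm as mp

landscape = mp.membrane_landscape(seed=5)
centers = np.array([-35.0, -25.0, -15.0, -5.0, 0.0, 5.0, 15.0, 25.0, 35.0])
dataset, _, truth_d = mp.generate_dataset(
    landscape, centers=centers, n_steps=400_000, base_seed=5
)

profile, estimates = mp.diffusion_profile(dataset)
print("  z (Å)   D_true (Å²/ps)   D_est (Å²/ps)    τ (ps)   ⟨δz²⟩ (Å²)")
for est in estimates:
    d_true = landscape.diffusivity(np.array([est.window_center]))[0]
    print(f"{est.window_center:7.1f} {d_true:15.4f} {est.D:15.4f} "
          f"{est.tau:9.2f} {est.msd_from_mean:11.3f}")

print()
print("τ grows ~10-fold where D drops: a restrained solute relaxes more")
print("slowly in the viscous membrane core while ⟨δz²⟩ stays near k_BT/k.")
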