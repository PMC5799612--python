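"""Orientation order parameters and solvation-shell counts.

Draws molecular-orientation samples at increasing alignment strengths
and summarizes them with the circular mean angle and the second-rank
order parameter; then builds coordinate frames with a known number of
oxygens planted inside the 4.25 Å contact shell and counts them back
with the minimum-image nearest-contact rule.
"""

import numpy as np

import memperm as mp

print("alignment λ    ⟨θ⟩ (deg)    S")
for lam in (0.0, 2.0, 10.0, 100.0):
    theta = mp.sample_orientations(lam, 50_000, seed=int(lam) + 1)
    vecs = np.stack([np.sin(theta), np.zeros_like(theta), np.cos(theta)], axis=1)
    solute = np.zeros((theta.size, 2, 3))
    solute[:, 1, :] = vecs
    solute += 50.0
    frames = mp.FrameSet(solute=solute, oxygens={}, n1_index=0, s_index=1,
                         box=np.array([100.0, 100.0, 100.0]))
    st = mp.orientation_stats(frames)
    print(f"{lam:10.1f} {st.mean_theta:11.1f} {st.order_parameter:8.3f}")
print("S runs from 0 (isotropic tumbling) toward 1 (locked along the")
print("membrane normal); S < 0 would mean in-plane orientation.\n")

frames = mp.build_frames(
    n_frames=5,
    n_oxygens={"water": 30, "phosphate": 8, "ester": 6},
    planted_contacts={"water": 3, "phosphate": 2, "ester": 0},
    box=(30.0, 30.0, 30.0),
    seed=9,
)
counts = mp.solvation_numbers(frames, cutoff=4.25)
print("mean solvation numbers (planted 3 water, 2 phosphate, 0 ester):")
for name, value in counts.mean().items():
    print(f"  {name:10s} {value:.1f}")

g = mp.site_rdf(frames, "water", bin_width=0.5, r_max=10.0)
peak_r = g.z_grid[np.argmax(g.values)]
print(f"\nsite RDF peaks at r = {peak_r:.2f} Å — inside the 4.25 Å shell, where")
print("the planted contacts sit; for real data the cutoff is read off the")
print("first minimum of exactly this curve.")
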