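"""Quantifying a kinase expression gradient from per-cell intensities.

Generates five replicate per-cell staining profiles emulating the Fj
gradient of the wing disc (peak 100 units distally, 3% geometric decay per
cell moving proximally, uniform background of 5 units estimated from
background-only "null clone" cells, Gaussian noise), then recovers the
per-adjacent-cell percent slope with its 95% confidence interval.
"""

from ftds import gradient as gq
from ftds import synth as sy

frame, truth = sy.gen_gradient_profiles(
    sy.SynthGradientSpec(n_cells=30, slope_frac=0.03, noise_sd=1.0,
                         n_profiles=5, clone_cells=(0, 1), seed=8)
)

profiles, background = [], None
non_clone = frame[frame["is_clone"] == 0]
background = frame[frame["is_clone"] == 1]["intensity"].mean()
for _, sub in non_clone.groupby("profile_id"):
    profiles.append(sub.sort_values("cell_index")["intensity"].to_numpy())

result = gq.gradient_from_profiles(profiles, background)
lo, hi = result["ci"]
print(f"clone-estimated background: {background:.2f} units")
print(
    f"mean per-cell slope: {result['mean_slope_pct']:+.2f}%/cell "
    f"(95% CI {lo:+.2f} to {hi:+.2f}, n={result['n']} profiles)"
)
print(f"generator truth: {truth['slope_pct']:+.2f}%/cell")
print(
    "\nA positive slope means intensity rises toward the distal end; the\n"
    "recovered ~3%/cell step is the per-cell difference a polarising cell\n"
    "must read out against the full expression level."
)
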