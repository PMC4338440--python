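"""FRAP stability pipeline on synthetic recoveries of two genotypes.

Generates bleach-corrected recovery traces for a "wild-type" (plateau 0.78,
pre-bleach 500 units) and a dimmer "mutant" (same stable fraction, half the
intensity), fits one-phase exponential associations, aggregates ROIs to
wings to genotypes, and compares wing-level stable amounts with an unpaired
t-test. The stable amount (stable fraction x pre-bleach intensity) separates
the genotypes even though their stable fractions are identical.
"""

import numpy as np

from ftds import frap as fq
from ftds import synth as sy


def analyse(spec: sy.SynthFrapSpec) -> list[fq.FrapFit]:
    traces, _ = sy.gen_frap_traces(spec)
    return [
        fq.fit_recovery(
            fq.normalize_to_prebleach(fq.correct_acquisition_bleaching(t))
        )
        for t in traces
    ]


wild_type = analyse(
    sy.SynthFrapSpec(plateau=0.78, prebleach_mean=500.0, noise_sd_frac=0.02,
                     acq_bleach_per_frame=0.002, n_rois=8, n_wings=6, seed=1)
)
mutant = analyse(
    sy.SynthFrapSpec(plateau=0.78, prebleach_mean=250.0, noise_sd_frac=0.02,
                     acq_bleach_per_frame=0.002, n_rois=8, n_wings=6, seed=2)
)

fit = wild_type[0]
print(
    f"example ROI fit: plateau {fit.plateau:.3f}, stable fraction "
    f"{fit.stable_fraction:.3f}, half-time {fit.half_time:.1f} s"
)

groups = {}
for name, fits in (("wild_type", wild_type), ("mutant", mutant)):
    summary = fq.aggregate_wings(fits, group_key=lambda f: name)
    row = summary.iloc[0]
    print(
        f"{name:>9}: stable amount {row.mean_stable_amount:6.1f} "
        f"+/- {row.sem_stable_amount:.1f} (SEM over {row.n_wings} wings)"
    )
    groups[name] = summary.attrs["wing_stable_amounts"][name]

report = fq.compare_groups(groups, design="two_group")
comp = report["comparisons"][0]
print(
    f"unpaired t-test: difference {comp['mean_difference']:.1f} units, "
    f"p = {comp['p_value']:.2g}"
)
print(
    "\nEqual stable fractions but a twofold intensity difference halve the\n"
    "mutant's stable amount: intensity scaling is what makes genotypes with\n"
    "different expression levels comparable."
)
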