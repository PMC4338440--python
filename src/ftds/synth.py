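"""Seeded ground-truth generators for every input the analysis stages consume.

These emulate extracted microscopy tables, not images: one-phase exponential
FRAP recoveries with multiplicative acquisition bleaching and additive
Gaussian noise; per-cell exponential-decay expression profiles with a
uniform background and background-only "clone" cells; and geometrically
decaying antibody-internalisation time courses. Every generator is
deterministic given its seed, and every noiseless output is recovered
exactly by its analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ftds.frap import DEFAULT_SCHEDULE, FrapTrace
from ftds.gradient import InternalisationCourse

__all__ = [
    "SynthFrapSpec",
    "SynthGradientSpec",
    "gen_frap_traces",
    "gen_gradient_profiles",
    "gen_internalisation_course",
    "traces_to_frame",
    "profiles_to_frame",
]


@dataclass
class SynthFrapSpec:
    """Generating parameters for synthetic FRAP traces.

    Defaults mirror the acquisition protocol and the worked stability
    example: recovery to a plateau of 0.78 (stable fraction 0.22) at
    0.02 s^-1 from a pre-bleach intensity of 500 units, sampled on the
    10x5 s + 10x10 s + 10x30 s schedule.
    """

    y0: float = 0.1
    plateau: float = 0.78
    rate_k: float = 0.02
    prebleach_mean: float = 500.0
    noise_sd_frac: float = 0.02
    acq_bleach_per_frame: float = 0.0
    schedule: np.ndarray = field(default_factory=lambda: DEFAULT_SCHEDULE.copy())
    n_rois: int = 8
    n_wings: int = 1
    region_class: str = "puncta"
    seed: int = 0

    def __post_init__(self):
        self.schedule = np.asarray(self.schedule, dtype=float)
        if not (0.0 <= self.plateau <= 1.5):
            raise ValueError("plateau must lie in [0, 1.5]")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")
        if not (0.0 <= self.acq_bleach_per_frame < 1.0):
            raise ValueError("acq_bleach_per_frame must lie in [0, 1)")
        if np.any(np.diff(self.schedule) <= 0):
            raise ValueError("schedule must be strictly increasing")
        if self.rate_k <= 0 or self.prebleach_mean <= 0:
            raise ValueError("rate_k and prebleach_mean must be positive")
        if self.n_rois < 1 or self.n_wings < 1:
            raise ValueError("n_rois and n_wings must be positive")


@dataclass
class SynthGradientSpec:
    """Generating parameters for synthetic per-cell expression profiles.

    Non-clone cell i carries ``peak * (1 - slope_frac)^d + background``
    where d is the distance from the distal end; clone cells carry
    background only. Defaults emulate the measured ~3%/cell proximo-distal
    expression gradient over a 30-cell row.
    """

    n_cells: int = 30
    peak_intensity: float = 100.0
    slope_frac: float = 0.03
    background: float = 5.0
    clone_cells: tuple = ()
    noise_sd: float = 0.0
    n_profiles: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.slope_frac < 1.0):
            raise ValueError("slope_frac must lie in [0, 1)")
        if self.noise_sd < 0 or self.background < 0 or self.peak_intensity <= 0:
            raise ValueError("invalid intensity parameters")
        if self.n_cells < 3 or self.n_profiles < 1:
            raise ValueError("need at least 3 cells and 1 profile")
        if any(not (0 <= c < self.n_cells) for c in self.clone_cells):
            raise ValueError("clone cell indices out of range")


def gen_frap_traces(spec: SynthFrapSpec) -> tuple[list[FrapTrace], dict]:
    """Generate bleached-ROI traces plus matched non-bleached references.

    Each post-bleach frame j is attenuated by the cumulative acquisition
    bleach factor ``(1 - acq_bleach_per_frame)^j``; the matched reference
    ROI carries only that factor (and noise), so dividing by it restores the
    bleach-free curve. Returns the traces and a truth record of all
    generating parameters.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.schedule
    curve = spec.y0 + (spec.plateau - spec.y0) * (1.0 - np.exp(-spec.rate_k * t))
    bleach = (1.0 - spec.acq_bleach_per_frame) ** np.arange(t.size)
    noise_sd = spec.noise_sd_frac * spec.prebleach_mean
    traces = []
    for w in range(spec.n_wings):
        for r in range(spec.n_rois):
            pre = spec.prebleach_mean + rng.normal(0.0, noise_sd, size=2)
            signal = curve * spec.prebleach_mean * bleach
            signal = signal + rng.normal(0.0, noise_sd, size=t.size)
            reference = spec.prebleach_mean * bleach + rng.normal(
                0.0, noise_sd, size=t.size
            )
            traces.append(
                FrapTrace(
                    roi_id=f"wing{w}_roi{r}",
                    wing_id=f"wing{w}",
                    region_class=spec.region_class,
                    times=t.copy(),
                    intensities=np.clip(signal, 0.0, None),
                    prebleach_intensities=np.clip(pre, 0.0, None),
                    reference_intensities=np.clip(reference, 1e-9, None),
                )
            )
    truth = {
        "y0": spec.y0,
        "plateau": spec.plateau,
        "stable_fraction": 1.0 - spec.plateau,
        "rate_k": spec.rate_k,
        "half_time": float(np.log(2.0) / spec.rate_k),
        "prebleach_mean": spec.prebleach_mean,
        "stable_amount": (1.0 - spec.plateau) * spec.prebleach_mean,
        "noise_sd_frac": spec.noise_sd_frac,
        "acq_bleach_per_frame": spec.acq_bleach_per_frame,
        "n_rois": spec.n_rois,
        "n_wings": spec.n_wings,
        "seed": spec.seed,
    }
    return traces, truth


def gen_gradient_profiles(spec: SynthGradientSpec) -> tuple[pd.DataFrame, dict]:
    """Generate replicate per-cell intensity profiles as CSV-shaped rows.

    Returns a DataFrame with columns ``profile_id, cell_index, intensity,
    is_clone`` (the schema :func:`ftds.gradient.read_profiles_csv` reads)
    and a truth record. Cell index 0 is proximal; the distal-most non-clone
    cell carries the peak intensity.
    """
    rng = np.random.default_rng(spec.seed)
    distance_from_distal = np.arange(spec.n_cells - 1, -1, -1, dtype=float)
    clean = (
        spec.peak_intensity * (1.0 - spec.slope_frac) ** distance_from_distal
        + spec.background
    )
    is_clone = np.zeros(spec.n_cells, dtype=int)
    is_clone[list(spec.clone_cells)] = 1
    rows = []
    for p in range(spec.n_profiles):
        noise = rng.normal(0.0, spec.noise_sd, size=spec.n_cells)
        values = np.where(is_clone == 1, spec.background, clean) + noise
        for i in range(spec.n_cells):
            rows.append(
                {
                    "profile_id": f"profile{p}",
                    "cell_index": i,
                    "intensity": max(values[i], 0.0),
                    "is_clone": int(is_clone[i]),
                }
            )
    truth = {
        # proximal-base percent change per cell of the rising geometric profile
        "slope_pct": 100.0 * spec.slope_frac / (1.0 - spec.slope_frac),
        "peak_intensity": spec.peak_intensity,
        "background": spec.background,
        "n_cells": spec.n_cells,
        "n_profiles": spec.n_profiles,
        "seed": spec.seed,
    }
    return pd.DataFrame(rows), truth


def gen_internalisation_course(
    retention_frac: float,
    t0_mean: float = 110.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    times: Sequence[float] = (0.0, 10.0, 20.0),
) -> tuple[InternalisationCourse, dict]:
    """Generate a surface-label internalisation time course.

    The above-background signal decays geometrically, retaining
    ``retention_frac`` of its value every 10 minutes.
    """
    if not (0.0 < retention_frac <= 1.0):
        raise ValueError("retention_frac must lie in (0, 1]")
    if t0_mean <= background:
        raise ValueError("t0_mean must exceed background")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    means = background + (t0_mean - background) * retention_frac ** (t / 10.0)
    means = means + rng.normal(0.0, noise_sd, size=t.size)
    course = InternalisationCourse(
        times=t, mean_intensities=means, laser_off_background=background
    )
    truth = {
        "retention_frac": retention_frac,
        "normalized_true": (retention_frac ** (t / 10.0)).tolist(),
        "seed": seed,
    }
    return course, truth


def traces_to_frame(traces: Sequence[FrapTrace]) -> pd.DataFrame:
    """Serialise traces into the long CSV schema read by the FRAP pipeline."""
    rows = []
    for tr in traces:
        for phase, times, values in (
            ("prebleach", (-2.0, -1.0), tr.prebleach_intensities),
            ("postbleach", tr.times, tr.intensities),
            (
                "reference",
                tr.times,
                tr.reference_intensities
                if tr.reference_intensities is not None
                else (),
            ),
        ):
            for t, v in zip(times, values):
                rows.append(
                    {
                        "wing_id": tr.wing_id,
                        "roi_id": tr.roi_id,
                        "region_class": tr.region_class,
                        "phase": phase,
                        "time_s": t,
                        "intensity": v,
                        "settings": tr.settings,
                    }
                )
    return pd.DataFrame(rows)


def profiles_to_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Identity passthrough kept for CLI symmetry; profiles are already rows."""
    return frame
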