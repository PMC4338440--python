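"""FRAP quantification: recovery-curve fitting and junctional-stability metrics.

Fluorescence recovery after photobleaching (FRAP) is used as an in vivo
binding assay for junctional cadherins: a region of interest (ROI) on a cell
junction is bleached and the return of fluorescence is recorded. The mobile
(unstable) protein fraction recovers; stably bound protein does not. The
pipeline is:

1. divide each trace by a matched non-bleached reference trace to undo
   acquisition bleaching (:func:`correct_acquisition_bleaching`);
2. normalise to the mean of the two pre-bleach images
   (:func:`normalize_to_prebleach`);
3. fit a one-phase exponential association
   ``y(t) = y0 + (plateau - y0) * (1 - exp(-rate_k * t))``
   (:func:`fit_recovery`). The plateau is the mobile fraction; the stable
   fraction is ``1 - plateau``; multiplying by the pre-bleach intensity gives
   the *stable amount* in raw intensity units (so genotypes with different
   expression levels can be compared at fixed microscope settings); the
   half-time of the mobile pool is ``ln(2)/rate_k``;
4. aggregate ROIs -> wing -> genotype (:func:`aggregate_wings`) and compare
   genotypes with unpaired t-tests or one-way ANOVA + Tukey
   (:func:`compare_groups`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lmfit import Model
from scipy import stats

__all__ = [
    "FrapTrace",
    "FrapFit",
    "correct_acquisition_bleaching",
    "normalize_to_prebleach",
    "fit_recovery",
    "stable_amount",
    "half_time",
    "aggregate_wings",
    "compare_groups",
    "read_traces_csv",
    "fits_to_frame",
    "DEFAULT_SCHEDULE",
]

REGION_CLASSES = ("puncta", "non_puncta", "junction")

#: post-bleach acquisition schedule in seconds: 10 frames every 5 s,
#: 10 every 10 s, then 10 every 30 s, with t = 0 at the first frame.
DEFAULT_SCHEDULE = np.concatenate(
    [
        np.arange(10) * 5.0,
        50.0 + np.arange(1, 11) * 10.0,
        150.0 + np.arange(1, 11) * 30.0,
    ]
)


@dataclass
class FrapTrace:
    """One bleached-ROI recovery time series.

    ``times`` are seconds from the first post-bleach frame (first entry 0).
    ``prebleach_intensities`` holds the two pre-bleach images.
    ``reference_intensities``, if present, is a matched non-bleached ROI used
    to correct acquisition bleaching. ``settings`` tags the microscope
    configuration; stable amounts are only comparable within one tag.
    """

    roi_id: str
    times: np.ndarray
    intensities: np.ndarray
    prebleach_intensities: np.ndarray
    wing_id: str = "wing0"
    region_class: str = "junction"
    reference_intensities: Optional[np.ndarray] = None
    settings: str = "default"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.prebleach_intensities = np.asarray(
            self.prebleach_intensities, dtype=float
        )
        if self.reference_intensities is not None:
            self.reference_intensities = np.asarray(
                self.reference_intensities, dtype=float
            )
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region_class {self.region_class!r}")
        if self.times.size != self.intensities.size:
            raise ValueError("times and intensities must have equal length")
        if self.times.size and self.times[0] != 0.0:
            raise ValueError("times must start at 0 (first post-bleach frame)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        if self.prebleach_intensities.size != 2:
            raise ValueError("exactly two pre-bleach intensities are required")

    @property
    def prebleach_mean(self) -> float:
        return float(self.prebleach_intensities.mean())


@dataclass
class FrapFit:
    """Fitted one-phase association parameters and derived stability metrics."""

    roi_id: str
    plateau: float
    rate_k: float
    y0: float
    prebleach_mean: float
    wing_id: str = "wing0"
    region_class: str = "junction"
    settings: str = "default"
    rate_ci: tuple[float, float] | None = None
    goodness: dict = field(default_factory=dict)

    @property
    def stable_fraction(self) -> float:
        """Immobile fraction: the complement of the recovery plateau."""
        return 1.0 - self.plateau

    @property
    def stable_amount(self) -> float:
        """Stable fraction scaled back to raw pre-bleach intensity units."""
        return self.stable_fraction * self.prebleach_mean

    @property
    def half_time(self) -> float:
        """Seconds to 50% recovery of the mobile pool: ln(2)/rate."""
        if self.rate_k <= 0:
            raise ValueError("half_time requires a positive rate_k")
        return math.log(2.0) / self.rate_k

    @property
    def half_time_ci(self) -> tuple[float, float] | None:
        """Half-time interval propagated from the rate confidence interval."""
        if self.rate_ci is None:
            return None
        lo_k, hi_k = self.rate_ci
        if lo_k <= 0:
            return (math.log(2.0) / hi_k, math.inf)
        return (math.log(2.0) / hi_k, math.log(2.0) / lo_k)


def correct_acquisition_bleaching(trace: FrapTrace) -> FrapTrace:
    """Divide out acquisition bleaching measured in a non-bleached region.

    The reference trace is normalised to its own first value, so a flat
    reference leaves the trace unchanged. Pre-bleach values are not
    corrected: they precede the post-bleach acquisition series.
    """
    ref = trace.reference_intensities
    if ref is None:
        raise ValueError(
            "trace has no reference_intensities; pass the trace through "
            "uncorrected only by explicit choice (corrected=False downstream)"
        )
    if ref.size != trace.times.size:
        raise ValueError("reference must match the post-bleach time base")
    if np.any(ref <= 0):
        raise ValueError("reference intensities must be positive")
    factor = ref / ref[0]
    out = replace(trace, intensities=trace.intensities / factor)
    out.reference_intensities = None
    out.metadata = dict(trace.metadata, bleach_corrected=True)
    return out


def normalize_to_prebleach(trace: FrapTrace) -> FrapTrace:
    """Scale intensities to the mean of the two pre-bleach images."""
    pre = trace.prebleach_mean
    if pre <= 0:
        raise ValueError("pre-bleach mean must be positive")
    out = replace(trace, intensities=trace.intensities / pre)
    out.metadata = dict(trace.metadata, normalized=True, prebleach_mean=pre)
    return out


def _association(t, y0, plateau, rate_k):
    return y0 + (plateau - y0) * (1.0 - np.exp(-rate_k * t))


_ASSOCIATION_MODEL = Model(_association)


def fit_recovery(trace: FrapTrace, anchor_y0: bool = False) -> FrapFit:
    """Least-squares fit of a one-phase exponential association curve.

    Expects a bleach-corrected, pre-bleach-normalised trace with at least 8
    post-bleach points. ``plateau`` is bounded at 1.5 rather than 1.0 so that
    over-recovery registers as a flagged fit instead of a silent clamp.
    With ``anchor_y0`` the immediate post-bleach intensity is held fixed
    instead of fitting the floor.
    """
    y = trace.intensities
    t = trace.times
    if t.size < 8:
        raise ValueError("need at least 8 post-bleach points to fit")
    params = _ASSOCIATION_MODEL.make_params(
        y0=dict(value=float(np.clip(y[0], 0.0, 1.0)), min=0.0, max=1.0),
        plateau=dict(value=float(np.clip(y[-5:].mean(), 0.0, 1.5)), min=0.0, max=1.5),
        rate_k=dict(value=0.02, min=1e-8),
    )
    if anchor_y0:
        params["y0"].set(vary=False)
    result = _ASSOCIATION_MODEL.fit(y, params, t=t)
    if not result.success:
        raise RuntimeError(
            f"recovery fit failed for ROI {trace.roi_id}: {result.message}; "
            f"residual norm {np.linalg.norm(result.residual):.4g}"
        )
    plateau = float(result.params["plateau"].value)
    rate_k = float(result.params["rate_k"].value)
    y0 = float(result.params["y0"].value)
    rate_err = result.params["rate_k"].stderr
    goodness = {
        "chisqr": float(result.chisqr),
        "redchi": float(result.redchi),
        "nfev": int(result.nfev),
        "flags": [],
    }
    if plateau >= 1.5 - 1e-9:
        goodness["flags"].append("plateau_at_upper_bound")
    # flat traces leave the rate unidentifiable: plateau == y0 makes the
    # exponential term drop out of the model entirely
    if abs(plateau - y0) < 1e-8 or rate_err is None or not np.isfinite(rate_err):
        goodness["flags"].append("rate_unidentifiable")
        rate_ci = None
    else:
        half_width = 1.96 * float(rate_err)
        rate_ci = (rate_k - half_width, rate_k + half_width)
    prebleach_mean = trace.metadata.get("prebleach_mean", trace.prebleach_mean)
    return FrapFit(
        roi_id=trace.roi_id,
        wing_id=trace.wing_id,
        region_class=trace.region_class,
        settings=trace.settings,
        plateau=plateau,
        rate_k=rate_k,
        y0=y0,
        prebleach_mean=float(prebleach_mean),
        rate_ci=rate_ci,
        goodness=goodness,
    )


def stable_amount(fit: FrapFit) -> float:
    """Stable fraction x pre-bleach intensity, in raw intensity units.

    For example a stable fraction of 0.22 at a pre-bleach intensity of 500
    units gives a stable amount of 110 units.
    """
    if not np.isfinite(fit.prebleach_mean):
        raise ValueError("fit carries no pre-bleach mean")
    return fit.stable_amount


def half_time(fit: FrapFit) -> float:
    """Time to 50% recovery of the mobile pool, ln(2)/rate_k, in seconds."""
    return fit.half_time


def aggregate_wings(
    fits: Iterable[FrapFit],
    group_key=lambda fit: fit.region_class,
) -> pd.DataFrame:
    """ROIs -> wing -> group aggregation of stable amounts.

    Within each wing the plateau is averaged over its ROIs and the pre-bleach
    intensity averaged likewise; the wing's stable amount is
    ``(1 - mean plateau) * mean pre-bleach``. Group statistics (mean, SEM)
    are then taken across wing stable amounts -- exactly this order, so a
    single bright ROI cannot dominate a genotype mean. Mixing microscope
    settings within a group is refused.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to aggregate")
    records = [
        {
            "group": group_key(f),
            "wing_id": f.wing_id,
            "plateau": f.plateau,
            "prebleach_mean": f.prebleach_mean,
            "settings": f.settings,
        }
        for f in fits
    ]
    frame = pd.DataFrame(records)
    for group, sub in frame.groupby("group"):
        if sub["settings"].nunique() > 1:
            raise ValueError(
                f"group {group!r} mixes microscope settings "
                f"{sorted(sub['settings'].unique())}; stable amounts are "
                "only comparable at identical settings"
            )
    wings = (
        frame.groupby(["group", "wing_id"], sort=False)
        .agg(plateau=("plateau", "mean"), prebleach=("prebleach_mean", "mean"))
        .reset_index()
    )
    wings["stable_amount"] = (1.0 - wings["plateau"]) * wings["prebleach"]
    out = (
        wings.groupby("group", sort=False)
        .agg(
            n_wings=("wing_id", "nunique"),
            mean_stable_amount=("stable_amount", "mean"),
            sem_stable_amount=("stable_amount", "sem"),
            mean_plateau=("plateau", "mean"),
            mean_prebleach=("prebleach", "mean"),
        )
        .reset_index()
    )
    out["sem_stable_amount"] = out["sem_stable_amount"].fillna(0.0)
    out.attrs["wing_stable_amounts"] = {
        group: sub["stable_amount"].tolist()
        for group, sub in wings.groupby("group", sort=False)
    }
    return out


def compare_groups(
    groups: Mapping[str, Sequence[float]] | pd.DataFrame,
    design: str = "two_group",
    alpha: float = 0.05,
) -> dict:
    """Compare wing-level stable amounts between genotypes.

    ``two_group`` delegates to an unpaired two-sided t-test, ``multi_group``
    to one-way ANOVA followed by Tukey's HSD for pairwise comparisons. Input
    is a mapping of group name to wing stable amounts, or the DataFrame
    returned by :func:`aggregate_wings` (its wing-level values travel in
    ``attrs``).
    """
    if isinstance(groups, pd.DataFrame):
        data = groups.attrs.get("wing_stable_amounts")
        if data is None:
            raise ValueError("DataFrame lacks wing-level stable amounts")
        data = {k: np.asarray(v, dtype=float) for k, v in data.items()}
    else:
        data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(data) < 2:
        raise ValueError("need at least two groups")
    for name, values in data.items():
        if len(values) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 wings")
    names = list(data)
    means = {name: float(np.mean(v)) for name, v in data.items()}
    report = {"design": design, "alpha": alpha, "group_means": means}
    if design == "two_group":
        if len(data) != 2:
            raise ValueError("two_group design requires exactly two groups")
        a, b = (data[n] for n in names)
        t_stat, p = stats.ttest_ind(a, b)
        report["comparisons"] = [
            {
                "groups": tuple(names),
                "mean_difference": means[names[0]] - means[names[1]],
                "statistic": float(t_stat),
                "p_value": float(p),
                "reject": bool(p < alpha),
            }
        ]
    elif design == "multi_group":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        f_stat, f_p = stats.f_oneway(*data.values())
        report["anova"] = {"statistic": float(f_stat), "p_value": float(f_p)}
        values = np.concatenate([data[n] for n in names])
        labels = np.concatenate([[n] * len(data[n]) for n in names])
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        report["comparisons"] = [
            {
                "groups": (g1, g2),
                "mean_difference": float(diff),
                "p_value": float(p_adj),
                "reject": bool(rej),
            }
            for (g1, g2, diff, p_adj, rej) in zip(
                tukey.groupsunique[tukey._multicomp.pairindices[0]],
                tukey.groupsunique[tukey._multicomp.pairindices[1]],
                tukey.meandiffs,
                tukey.pvalues,
                tukey.reject,
            )
        ]
    else:
        raise ValueError(f"unknown design {design!r}")
    return report


def read_traces_csv(path) -> list[FrapTrace]:
    """Read FRAP traces from the long-format CSV schema.

    Required columns: ``wing_id, roi_id, region_class, phase, time_s,
    intensity`` with ``phase`` one of ``prebleach``, ``postbleach`` or
    ``reference``; an optional ``settings`` column tags the microscope
    configuration.
    """
    frame = pd.read_csv(path)
    required = {"wing_id", "roi_id", "region_class", "phase", "time_s", "intensity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"traces CSV is missing columns {sorted(missing)}")
    traces = []
    for (wing_id, roi_id), sub in frame.groupby(["wing_id", "roi_id"], sort=False):
        pre = sub[sub["phase"] == "prebleach"]["intensity"].to_numpy()
        post = sub[sub["phase"] == "postbleach"].sort_values("time_s")
        ref = sub[sub["phase"] == "reference"].sort_values("time_s")
        settings = (
            str(sub["settings"].iloc[0]) if "settings" in sub.columns else "default"
        )
        traces.append(
            FrapTrace(
                roi_id=str(roi_id),
                wing_id=str(wing_id),
                region_class=str(sub["region_class"].iloc[0]),
                times=post["time_s"].to_numpy(),
                intensities=post["intensity"].to_numpy(),
                prebleach_intensities=pre,
                reference_intensities=(
                    ref["intensity"].to_numpy() if len(ref) else None
                ),
                settings=settings,
            )
        )
    return traces


def fits_to_frame(fits: Iterable[FrapFit]) -> pd.DataFrame:
    """Tabulate per-ROI fit results for CSV export."""
    rows = []
    for f in fits:
        ci = f.half_time_ci
        rows.append(
            {
                "wing_id": f.wing_id,
                "roi_id": f.roi_id,
                "region_class": f.region_class,
                "plateau": f.plateau,
                "stable_fraction": f.stable_fraction,
                "rate_k": f.rate_k,
                "half_time_s": (
                    f.half_time if f.rate_k > 0 else np.nan
                ),
                "half_time_ci_low": ci[0] if ci else np.nan,
                "half_time_ci_high": ci[1] if ci else np.nan,
                "prebleach_mean": f.prebleach_mean,
                "stable_amount": f.stable_amount,
                "flags": ";".join(f.goodness.get("flags", [])),
            }
        )
    return pd.DataFrame(rows)
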