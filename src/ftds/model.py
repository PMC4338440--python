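"""1D mass-action model of Ft-Ds heterodimer formation under a Four-jointed gradient.

A row of ``n_cells`` epithelial cells is modelled, each with a proximal (P)
and distal (D) membrane compartment. The Golgi kinase Four-jointed (Fj) is
expressed in a linear proximo-distal gradient and phosphorylates the
extracellular cadherin repeats of Fat (Ft) and/or Dachsous (Ds) before the
molecules reach the cell surface. Phosphorylated and unphosphorylated forms
then bind across each cell-cell junction, forming four complex species in
two orientations per junction:

    A = FtP-Ds   (strongest)
    B = FtP-DsP
    C = Ft-Ds
    D = Ft-DsP   (weakest, under the initial affinity hierarchy)

where the ``P`` suffix marks the phosphorylated form. Binding and unbinding
follow mass action; free molecules additionally redistribute between the two
membranes of a cell at rate ``diff``. Integrating to steady state yields the
planar-polarised distribution of bound Ft and Ds: with a positive Fj slope,
bound Ds accumulates distally and bound Ft proximally in every interior cell.

Two affinity hierarchies are provided as presets, expressed as association
constants (k_on/k_off) relative to complex A:

* ``initial_hierarchy``: A > B = C > D with constants (1, 1/4, 1/4, 1/16) --
  Ds phosphorylation penalises binding regardless of partner.
* ``revised_hierarchy``: A > B > C = D with constants (1, 1/2, 1/4, 1/4) --
  Fj's effect on Ft dominates; DsP only matters when Ft is phosphorylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "AffinityPreset",
    "Scenario",
    "ModelParams",
    "FjActivityProfile",
    "CellRowState",
    "SteadyStateSummary",
    "ConvergenceError",
    "build_fj_profile",
    "initialize_state",
    "ode_rhs",
    "integrate_to_steady_state",
    "cell_asymmetry",
    "tissue_gradient",
    "run_scenario",
    "summarize_state",
    "target_species",
    "calibrated_params",
    "calibration_grid",
]

# complex/species index order used throughout the state arrays
COMPLEX_NAMES = ("A", "B", "C", "D")
FREE_NAMES = ("Ft", "FtP", "Ds", "DsP")
_FT, _FTP, _DS, _DSP = 0, 1, 2, 3
_P, _D = 0, 1

#: association constants k_on/k_off for complexes A-D, relative to A
PRESET_AFFINITIES = {
    "initial_hierarchy": (1.0, 0.25, 0.25, 1.0 / 16.0),
    "revised_hierarchy": (1.0, 0.5, 0.25, 0.25),
}


class AffinityPreset(str, Enum):
    initial_hierarchy = "initial_hierarchy"
    revised_hierarchy = "revised_hierarchy"
    custom = "custom"


class Scenario(str, Enum):
    ds_only = "ds_only"
    ft_only = "ft_only"
    both_equal = "both_equal"
    both_ft_biased = "both_ft_biased"


class ConvergenceError(RuntimeError):
    """Raised when the ODE system fails to reach steady state in time."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class ModelParams:
    """Parameters of the cell-row binding model.

    Rate constants are in arbitrary-concentration/time units; by convention
    all unbinding rates default to 1, so binding rates equal the association
    constants of the chosen hierarchy. ``diff`` is the intra-cell
    redistribution rate of free molecules between the two membranes of a
    cell. ``fj_slope`` is the per-cell step of the linear Fj-activity
    profile (0.03 reproduces the measured ~3% expression gradient).
    """

    n_cells: int = 23
    k_on_A: float = 1.0
    k_off_A: float = 1.0
    k_on_B: float = 0.25
    k_off_B: float = 1.0
    k_on_C: float = 0.25
    k_off_C: float = 1.0
    k_on_D: float = 1.0 / 16.0
    k_off_D: float = 1.0
    diff: float = 1.0
    fj_slope: float = 0.03
    fj_acts_on_ft: bool = True
    fj_acts_on_ds: bool = True
    ft_total_per_membrane: float = 50.0
    ds_total_per_membrane: float = 50.0
    affinity_preset: AffinityPreset = AffinityPreset.custom

    def __post_init__(self):
        self.affinity_preset = AffinityPreset(self.affinity_preset)
        if self.affinity_preset is not AffinityPreset.custom:
            k = PRESET_AFFINITIES[self.affinity_preset.value]
            self.k_on_A, self.k_on_B, self.k_on_C, self.k_on_D = k
            self.k_off_A = self.k_off_B = self.k_off_C = self.k_off_D = 1.0
        self._validate()

    def _validate(self):
        if self.n_cells < 2:
            raise ValueError("n_cells must be at least 2")
        if not (0.0 <= self.fj_slope < 1.0):
            raise ValueError("fj_slope must lie in [0, 1)")
        for name in COMPLEX_NAMES:
            k_on = getattr(self, f"k_on_{name}")
            k_off = getattr(self, f"k_off_{name}")
            if k_on < 0 or k_off < 0:
                raise ValueError(f"rate constants for complex {name} must be >= 0")
            if k_on > 0 and k_off == 0:
                raise ValueError(
                    f"complex {name}: k_off must be positive when k_on > 0"
                )
        if self.diff < 0:
            raise ValueError("diff must be >= 0")
        if self.ft_total_per_membrane < 0 or self.ds_total_per_membrane < 0:
            raise ValueError("initial amounts must be >= 0")

    @property
    def k_on(self) -> np.ndarray:
        return np.array([self.k_on_A, self.k_on_B, self.k_on_C, self.k_on_D])

    @property
    def k_off(self) -> np.ndarray:
        return np.array([self.k_off_A, self.k_off_B, self.k_off_C, self.k_off_D])


@dataclass
class FjActivityProfile:
    """Per-cell Fj activity (phosphorylated fraction), proximal to distal."""

    phi: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 1 or self.phi.size < 2:
            raise ValueError("phi must be a 1D array of at least 2 cells")
        if np.any(self.phi < 0) or np.any(self.phi > 1):
            raise ValueError("Fj activities must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.phi.size


def build_fj_profile(n_cells: int, fj_slope: float) -> FjActivityProfile:
    """Linear Fj-activity profile anchored at 1.0 in the distal-most cell.

    Cell ``i`` (0 = proximal) receives activity ``1 - fj_slope * (n - 1 - i)``,
    so adjacent cells differ by ``fj_slope`` of the peak activity -- the same
    convention as the expression-gradient measurement, where intensities are
    normalised to 100% in the brightest distal cells and the per-cell step is
    quoted as a percentage of that maximum.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be at least 2")
    if not (0.0 <= fj_slope < 1.0):
        raise ValueError("fj_slope must lie in [0, 1)")
    max_slope = 1.0 / (n_cells - 1)
    if fj_slope > max_slope:
        raise ValueError(
            f"fj_slope {fj_slope} too steep for {n_cells} cells: proximal "
            f"activity would fall below 0 (maximum admissible slope "
            f"{max_slope:.6g})"
        )
    phi = 1.0 - fj_slope * np.arange(n_cells - 1, -1, -1, dtype=float)
    return FjActivityProfile(phi=phi)


@dataclass
class CellRowState:
    """Amounts of all molecular species along the cell row.

    ``free`` has shape (4, n_cells, 2): species (Ft, FtP, Ds, DsP) by cell by
    membrane (P=0, D=1). ``cplx_p[k, i]`` is the amount of complex k resident
    at the proximal membrane of cell i -- cell i's Ft bound to cell i-1's Ds
    -- and is zero at i=0. ``cplx_d[k, i]`` is the distally resident
    orientation -- cell i's Ft bound to cell i+1's Ds -- zero at i=n-1.
    """

    free: np.ndarray
    cplx_p: np.ndarray
    cplx_d: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.free.shape[1]

    @classmethod
    def zeros(cls, n_cells: int) -> "CellRowState":
        return cls(
            free=np.zeros((4, n_cells, 2)),
            cplx_p=np.zeros((4, n_cells)),
            cplx_d=np.zeros((4, n_cells)),
        )

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.free.ravel(), self.cplx_p.ravel(), self.cplx_d.ravel()]
        )

    @classmethod
    def from_vector(cls, y: np.ndarray, n_cells: int) -> "CellRowState":
        n_free = 8 * n_cells
        n_cplx = 4 * n_cells
        free = y[:n_free].reshape(4, n_cells, 2)
        cplx_p = y[n_free : n_free + n_cplx].reshape(4, n_cells)
        cplx_d = y[n_free + n_cplx :].reshape(4, n_cells)
        return cls(free=free, cplx_p=cplx_p, cplx_d=cplx_d)

    def ft_total_per_cell(self) -> np.ndarray:
        """Total Ft-containing material per cell (free + complexed)."""
        return (
            self.free[_FT].sum(axis=1)
            + self.free[_FTP].sum(axis=1)
            + self.cplx_p.sum(axis=0)
            + self.cplx_d.sum(axis=0)
        )

    def ds_total_per_cell(self) -> np.ndarray:
        """Total Ds-containing material per cell (free + complexed).

        Cell i's Ds at its P membrane is held in the distally resident
        complexes of cell i-1, and its D-membrane Ds in the proximally
        resident complexes of cell i+1.
        """
        n = self.n_cells
        total = self.free[_DS].sum(axis=1) + self.free[_DSP].sum(axis=1)
        total[1:] += self.cplx_d[:, :-1].sum(axis=0)
        total[:-1] += self.cplx_p[:, 1:].sum(axis=0)
        return total


@dataclass
class SteadyStateSummary:
    """Per-cell bound amounts at steady state plus polarity metrics.

    ``bound_ds_P[i]`` / ``bound_ds_D[i]`` sum every complex containing cell
    i's Ds at its proximal / distal membrane; likewise for Ft. ``total_bound``
    is the per-cell sum over both membranes for the chosen species (Ds by
    default -- each trans-junction complex is counted once per side).
    """

    bound_ds_P: np.ndarray
    bound_ds_D: np.ndarray
    bound_ft_P: np.ndarray
    bound_ft_D: np.ndarray
    params: ModelParams
    residual: float
    metadata: dict = field(default_factory=dict)
    state: Optional[CellRowState] = None

    @property
    def n_cells(self) -> int:
        return self.bound_ds_P.size

    @property
    def interior(self) -> slice:
        return slice(1, self.n_cells - 1)

    def total_bound(self, species: str = "bound_ds") -> np.ndarray:
        if species == "bound_ds":
            return self.bound_ds_P + self.bound_ds_D
        if species == "bound_ft":
            return self.bound_ft_P + self.bound_ft_D
        raise ValueError(f"unknown species {species!r}")


def initialize_state(
    params: ModelParams, profile: FjActivityProfile
) -> CellRowState:
    """Partition the initial Ft and Ds pools into phosphorylated fractions.

    Each membrane of cell i starts with ``ft_total_per_membrane`` of Ft,
    split as FtP = phi_i * total when Fj acts on Ft (else all unmodified),
    and analogously for Ds. Phosphorylation is a one-shot Golgi event applied
    before surface delivery, so both membranes of a cell receive the same
    split and no interconversion occurs afterwards. All complexes start at 0.
    """
    if profile.n_cells != params.n_cells:
        raise ValueError(
            f"profile has {profile.n_cells} cells but params expect "
            f"{params.n_cells}"
        )
    state = CellRowState.zeros(params.n_cells)
    phi = profile.phi[:, None]  # broadcast over membranes
    ft, ds = params.ft_total_per_membrane, params.ds_total_per_membrane
    if params.fj_acts_on_ft:
        state.free[_FTP] = phi * ft
        state.free[_FT] = (1.0 - phi) * ft
    else:
        state.free[_FT] = ft
    if params.fj_acts_on_ds:
        state.free[_DSP] = phi * ds
        state.free[_DS] = (1.0 - phi) * ds
    else:
        state.free[_DS] = ds
    return state


def _rhs_arrays(state: CellRowState, params: ModelParams) -> CellRowState:
    """Mass-action derivatives of every species.

    Proximally resident complexes at cell i pair cell i's P-membrane Ft with
    cell i-1's D-membrane Ds; distally resident complexes mirror this. Free
    species lose their binding fluxes, gain the unbinding fluxes of the
    complexes that hold them, and exchange between the two membranes of a
    cell at rate ``diff``.
    """
    free, cp, cd = state.free, state.cplx_p, state.cplx_d
    k_on, k_off = params.k_on, params.k_off
    d = CellRowState.zeros(state.n_cells)

    # Ft partner for complexes A,B is FtP; for C,D it is Ft.
    # Ds partner for complexes A,C is Ds; for B,D it is DsP.
    ft_idx = (_FTP, _FTP, _FT, _FT)
    ds_idx = (_DS, _DSP, _DS, _DSP)

    for k in range(4):
        fi, di = ft_idx[k], ds_idx[k]
        # proximally resident: Ft of cell i (P membrane) x Ds of cell i-1 (D)
        bind_p = k_on[k] * free[fi, 1:, _P] * free[di, :-1, _D]
        unbind_p = k_off[k] * cp[k, 1:]
        d.cplx_p[k, 1:] = bind_p - unbind_p
        # distally resident: Ft of cell i (D membrane) x Ds of cell i+1 (P)
        bind_d = k_on[k] * free[fi, :-1, _D] * free[di, 1:, _P]
        unbind_d = k_off[k] * cd[k, :-1]
        d.cplx_d[k, :-1] = bind_d - unbind_d

        # the Ft side of the complex lives in the same cell as the complex
        d.free[fi, 1:, _P] += unbind_p - bind_p
        d.free[fi, :-1, _D] += unbind_d - bind_d
        # the Ds side lives in the neighbouring cell
        d.free[di, :-1, _D] += unbind_p - bind_p
        d.free[di, 1:, _P] += unbind_d - bind_d

    # intra-cell redistribution of free molecules between the two membranes
    if params.diff > 0:
        flux = params.diff * (free[:, :, _D] - free[:, :, _P])
        d.free[:, :, _P] += flux
        d.free[:, :, _D] -= flux
    return d


def ode_rhs(state: CellRowState, params: ModelParams) -> CellRowState:
    """Time derivative of the full state; validates the input state."""
    if state.n_cells != params.n_cells:
        raise ValueError("state dimensions do not match params")
    for arr in (state.free, state.cplx_p, state.cplx_d):
        if np.any(~np.isfinite(arr)):
            raise ValueError("state contains NaN or infinite entries")
        if np.any(arr < 0):
            raise ValueError("state contains negative amounts")
    return _rhs_arrays(state, params)


def _residual(y: np.ndarray, dy: np.ndarray) -> float:
    scale = max(float(np.max(np.abs(y))), 1.0)
    return float(np.max(np.abs(dy))) / scale


def integrate_to_steady_state(
    state: CellRowState,
    params: ModelParams,
    rtol: float = 1e-9,
    max_time: float = 1e6,
) -> SteadyStateSummary:
    """Integrate the binding system until the flow effectively stops.

    The system is stiff (binding fluxes ~k_on * 50 * 50 against unit
    unbinding rates), so an implicit BDF scheme is used, in doubling time
    windows, until ``max|dy/dt| / max(|y|, 1) < rtol``. The achieved residual
    is recorded on the summary.
    """
    if rtol <= 0:
        raise ValueError("rtol must be positive")
    n = params.n_cells
    ode_rhs(state, params)  # validates shapes and non-negativity
    y = state.to_vector()

    def f(t, y):
        s = CellRowState.from_vector(y, n)
        return _rhs_arrays(s, params).to_vector()

    t, window = 0.0, 10.0
    res = _residual(y, f(0.0, y))
    while res > rtol and t < max_time:
        t_end = min(t + window, max_time)
        sol = solve_ivp(
            f, (t, t_end), y, method="BDF", rtol=1e-10, atol=1e-10
        )
        if not sol.success:
            raise ConvergenceError(
                f"ODE solver failed: {sol.message}", residual=res
            )
        y = sol.y[:, -1]
        t = t_end
        window *= 2.0
        res = _residual(y, f(t, y))
    if res > rtol:
        raise ConvergenceError(
            f"no steady state within max_time={max_time}: residual {res:.3e}",
            residual=res,
        )
    final = CellRowState.from_vector(y, n)
    return summarize_state(final, params, residual=res)


def summarize_state(
    state: CellRowState, params: ModelParams, residual: float = float("nan")
) -> SteadyStateSummary:
    """Collect per-membrane bound amounts from a (steady) state."""
    cp_sum = state.cplx_p.sum(axis=0)
    cd_sum = state.cplx_d.sum(axis=0)
    n = state.n_cells
    bound_ds_P = np.zeros(n)
    bound_ds_D = np.zeros(n)
    bound_ds_P[1:] = cd_sum[:-1]  # cell i's P-membrane Ds sits in cell i-1's cd
    bound_ds_D[:-1] = cp_sum[1:]  # cell i's D-membrane Ds sits in cell i+1's cp
    return SteadyStateSummary(
        bound_ds_P=bound_ds_P,
        bound_ds_D=bound_ds_D,
        bound_ft_P=cp_sum.copy(),
        bound_ft_D=cd_sum.copy(),
        params=params,
        residual=residual,
        metadata={
            "asymmetry_base": "disfavoured_membrane",
            "convergence_residual": residual,
        },
        state=state,
    )


def cell_asymmetry(
    summary: SteadyStateSummary, species: str = "bound_ds", cell_index: int | None = None
) -> float:
    """Percent excess of bound protein at the favoured membrane of one cell.

    Bound Ds is favoured distally and bound Ft proximally (the polarity
    readout of the wing). Returns 100 * (favoured - disfavoured) /
    disfavoured, i.e. the "x% increase" convention with the smaller membrane
    amount as base. Defaults to the central cell.
    """
    n = summary.n_cells
    if cell_index is None:
        cell_index = n // 2
    if not (1 <= cell_index <= n - 2):
        raise ValueError(
            f"cell {cell_index} is terminal; asymmetry is defined for "
            f"interior cells 1..{n - 2}"
        )
    if species == "bound_ds":
        favoured = summary.bound_ds_D[cell_index]
        disfavoured = summary.bound_ds_P[cell_index]
    elif species == "bound_ft":
        favoured = summary.bound_ft_P[cell_index]
        disfavoured = summary.bound_ft_D[cell_index]
    else:
        raise ValueError(f"unknown species {species!r}")
    if disfavoured == 0:
        raise ValueError("disfavoured membrane amount is zero")
    return 100.0 * (favoured - disfavoured) / disfavoured


def tissue_gradient(
    summary: SteadyStateSummary,
    mode: str = "end_to_end",
    species: str = "bound_ds",
) -> float:
    """Percent gradient of total bound protein per cell along the row.

    ``per_cell_mean`` averages the adjacent-cell percent change over interior
    cells; ``end_to_end`` is the percent change from the first to the last
    interior cell. Terminal cells have only one junction and are excluded.
    Positive values mean binding increases towards high Fj (distally).
    """
    tb = summary.total_bound(species)[summary.interior]
    if tb.size < 3:
        raise ValueError("need at least 3 interior cells")
    if np.any(tb == 0):
        raise ValueError("zero total bound amount in an interior cell")
    if mode == "per_cell_mean":
        value = float(np.mean(100.0 * np.diff(tb) / tb[:-1]))
    elif mode == "end_to_end":
        value = float(100.0 * (tb[-1] - tb[0]) / tb[0])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    summary.metadata["tissue_gradient_mode"] = mode
    return value


def target_species(scenario: Scenario | str) -> str:
    """Headline asymmetry species for a scenario.

    The per-cell asymmetry readout is taken on the species whose
    phosphorylation state Fj modifies in that scenario; when Fj acts on both
    species, bound Ds -- the stronger experimental polarity readout -- is
    quoted.
    """
    scenario = Scenario(scenario)
    return "bound_ft" if scenario is Scenario.ft_only else "bound_ds"


def calibrated_params(**overrides) -> ModelParams:
    """Model parameters at the documented calibration point.

    ``diff`` and the initial per-membrane totals are not constrained by the
    published rate hierarchy, so they are fixed by a grid search (see
    :func:`calibration_grid`): ``diff = 1.0`` (the steady state is invariant
    to any positive redistribution rate) and 25 arbitrary units of Ft and Ds
    per membrane, which places per-membrane bound amounts in the 13-19 unit
    range of the model displays (scale cut off at 20 units).
    """
    defaults = dict(diff=1.0, ft_total_per_membrane=25.0, ds_total_per_membrane=25.0)
    defaults.update(overrides)
    return ModelParams(**defaults)


def calibration_grid(
    diffs=(0.1, 1.0, 10.0),
    totals=(25.0, 50.0, 100.0),
    n_cells: int = 23,
    fj_slope: float = 0.03,
):
    """Scan redistribution rates and initial totals over all four scenarios.

    Returns a DataFrame with one row per (diff, total, scenario) carrying
    central-cell asymmetries for both species plus the target-species
    readout, and both tissue-gradient metrics of total bound Ds.
    """
    import pandas as pd

    rows = []
    for diff in diffs:
        for total in totals:
            for scenario in Scenario:
                params = ModelParams(
                    n_cells=n_cells,
                    fj_slope=fj_slope,
                    diff=diff,
                    ft_total_per_membrane=total,
                    ds_total_per_membrane=total,
                )
                summary = run_scenario(scenario, params)
                rows.append(
                    {
                        "diff": diff,
                        "total_per_membrane": total,
                        "scenario": scenario.value,
                        "asym_ds_pct": cell_asymmetry(summary, "bound_ds"),
                        "asym_ft_pct": cell_asymmetry(summary, "bound_ft"),
                        "asym_target_pct": cell_asymmetry(
                            summary, target_species(scenario)
                        ),
                        "gradient_end_to_end_pct": tissue_gradient(
                            summary, "end_to_end"
                        ),
                        "gradient_per_cell_pct": tissue_gradient(
                            summary, "per_cell_mean"
                        ),
                    }
                )
    return pd.DataFrame(rows)


_SCENARIO_FLAGS = {
    Scenario.ds_only: (False, True),
    Scenario.ft_only: (True, False),
    Scenario.both_equal: (True, True),
    Scenario.both_ft_biased: (True, True),
}


def run_scenario(
    scenario: Scenario | str,
    params: ModelParams | None = None,
    rtol: float = 1e-9,
    max_time: float = 1e6,
) -> SteadyStateSummary:
    """Run one of the four Fj-action scenarios to steady state.

    ``ds_only``, ``ft_only`` and ``both_equal`` use the initial affinity
    hierarchy (1, 1/4, 1/4, 1/16); ``both_ft_biased`` uses the revised
    hierarchy (1, 1/2, 1/4, 1/4) in which Ft phosphorylation dominates.
    """
    scenario = Scenario(scenario)
    if params is None:
        params = ModelParams()
    preset = (
        AffinityPreset.revised_hierarchy
        if scenario is Scenario.both_ft_biased
        else AffinityPreset.initial_hierarchy
    )
    if params.affinity_preset not in (AffinityPreset.custom, preset):
        raise ValueError(
            f"scenario {scenario.value} is inconsistent with preset "
            f"{params.affinity_preset.value}"
        )
    acts_ft, acts_ds = _SCENARIO_FLAGS[scenario]
    params = replace(
        params,
        fj_acts_on_ft=acts_ft,
        fj_acts_on_ds=acts_ds,
        affinity_preset=preset,
    )
    profile = build_fj_profile(params.n_cells, params.fj_slope)
    state = initialize_state(params, profile)
    summary = integrate_to_steady_state(state, params, rtol=rtol, max_time=max_time)
    summary.metadata["scenario"] = scenario.value
    return summary
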