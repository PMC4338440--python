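# Methods

## The cell-row binding model

A row of `n_cells` cells (default 23) is modelled in one dimension. Each
cell *i* has a proximal (P) and a distal (D) membrane compartment carrying
free Ft, FtP, Ds and DsP (P-suffix = phosphorylated), in arbitrary
concentration units. Across each junction, the Ft of one cell binds the Ds
of its neighbour; all four phosphoform pairings are tracked as distinct
complexes, in both orientations per junction:

- A = FtP–Ds (strongest), B = FtP–DsP, C = Ft–Ds, D = Ft–DsP.

Binding and unbinding follow mass action. For the proximally resident
complexes of cell *i* (its Ft at its P membrane bound to cell *i−1*'s Ds at
that cell's D membrane):

```
dA_Pi/dt = ka_on·FtP_Pi·Ds_Di−1  − ka_off·A_Pi
dB_Pi/dt = kb_on·FtP_Pi·DsP_Di−1 − kb_off·B_Pi
dC_Pi/dt = kc_on·Ft_Pi·Ds_Di−1   − kc_off·C_Pi
dD_Pi/dt = kd_on·Ft_Pi·DsP_Di−1  − kd_off·D_Pi
```

with mirrored equations for distally resident complexes. Free species lose
their binding fluxes, gain the unbinding fluxes of the complexes that hold
them, and exchange between the two membranes of the same cell at rate
`diff`, e.g.

```
dDs_Pi/dt = −ka_on·FtP_Di−1·Ds_Pi − kc_on·Ft_Di−1·Ds_Pi
            + ka_off·A_Di−1 + kc_off·C_Di−1 + diff·(Ds_Di − Ds_Pi)
```

The row is not periodic: the P membrane of the first cell and the D
membrane of the last carry no complexes (free species still redistribute
there).

**Fj input.** Fj activity is a linear per-cell profile anchored at 1.0 in
the distal-most cell with per-cell step `fj_slope` (default 0.03, the
measured expression gradient); the maximum admissible slope for *n* cells
is 1/(n−1). φᵢ is interpreted directly as the phosphorylated fraction:
phosphorylation is a one-shot Golgi event applied before surface delivery,
so at t = 0 each membrane's pool is split FtP = φᵢ·total,
Ft = (1−φᵢ)·total when Fj acts on Ft (likewise for Ds), with no subsequent
interconversion. Anchoring at the distal maximum maximises dynamic range
while keeping all fractions in [0, 1].

**Affinity presets.** Association constants (k_on/k_off) of A–D relative to
A: `initial_hierarchy` (1, 1/4, 1/4, 1/16) encodes A > B = C > D (Ds
phosphorylation always penalises binding); `revised_hierarchy`
(1, 1/2, 1/4, 1/4) encodes A > B > C = D (Ft phosphorylation dominates;
DsP only matters when Ft is phosphorylated). All k_off default to 1, so
k_on equals the association constant; time is therefore measured in units
of the complex lifetime.

**Integration.** The system is stiff (binding fluxes of order
k_on·25·25 against unit unbinding rates), so it is integrated with an
implicit BDF scheme (scipy `solve_ivp`, rtol = atol = 1e−10) over doubling
time windows until the steady-state residual max|dy/dt| / max(|y|, 1)
drops below 1e−9. The achieved residual is recorded on the summary; per-cell
Ft and Ds material is conserved to better than 1e−6 relative throughout
(verified by test). Failure to converge raises an error carrying the final
residual.

**Readouts.**

- *Within-cell asymmetry* (percent): 100·(favoured − disfavoured)/
  disfavoured at one cell's two membranes, favoured being distal for bound
  Ds and proximal for bound Ft. The base is the smaller (disfavoured)
  membrane amount, recorded in metadata as `asymmetry_base`. The default
  cell is the central one. The headline species per scenario is the one
  whose phosphorylation Fj modifies there (Ds for `ds_only`, Ft for
  `ft_only`); when both are modified, bound Ds — the stronger experimental
  polarity readout — is quoted. Both species are always available.
- *Tissue gradient* (percent): computed on per-cell total bound Ds over the
  interior cells, either end-to-end (default headline metric;
  100·(last − first)/first) or as the mean of adjacent-cell percent
  changes. Both are implemented and reported because shallow per-cell
  changes and whole-field changes answer different questions.

**Calibration.** The affinity hierarchy fixes only ratios; the
redistribution rate and the initial amounts are free. They were fixed once
by a grid search (`calibration_grid()`: diff ∈ {0.1, 1, 10} × totals ∈
{25, 50, 100} per membrane, all four scenarios). Two findings:

1. *The steady state is invariant to any positive `diff`.* At stationarity
   the redistribution term only enforces equality of each free pool across
   a cell's membranes, whatever the rate, so the grid collapses along the
   diff axis. `diff = 1.0` (comparable to complex lifetime) is kept as the
   default; `diff` still controls approach dynamics.
2. *Totals = 25 per membrane* places steady-state per-membrane bound
   amounts in the 13–19 unit range — i.e. under a 20-unit display ceiling —
   and is adopted as the calibrated point, exposed as `calibrated_params()`.
   The general-purpose `ModelParams` default stays at 50 per membrane; a
   Ft:Ds = 2:1 loading can be configured to reflect the measured Ft excess.

**Edge behaviour.** Terminal cells feed a single junction, so their free
pools over-supply it; this creates an alternating deviation in bound
amounts that decays by roughly 0.4× per cell inward and is mirror-symmetric
at zero slope. Consequently: zero-slope symmetry is exact at the row centre
(central asymmetry < 1e−6; the full row obeys exact reflection symmetry)
but not cell-by-cell near the ends; the orientation rule (Ds distal / Ft
proximal) holds for cells ≥ 6 from an end at a 3% slope; and the per-cell
mean gradient retains a ~0.1% edge residue even at zero slope, while the
end-to-end metric vanishes exactly there. Metrics are restricted to
interior cells; the asymmetry readout uses the central cell, far from both
ends.

## FRAP quantification

Traces are per-ROI time series with exactly two pre-bleach images, t = 0 at
the first post-bleach frame, and the default acquisition schedule 10×5 s,
10×10 s, 10×30 s. The processing order is fixed: acquisition-bleach
correction first (divide by a matched non-bleached reference normalised to
its own first value — multiplicative correction; pre-bleach values are not
corrected since they precede the post-bleach series), then division by the
pre-bleach mean.

The recovery is fit by least squares (lmfit) to the one-phase exponential
association y(t) = y₀ + (plateau − y₀)(1 − e^(−kt)) with y₀ ∈ [0, 1],
plateau ∈ [0, 1.5], k > 0. The floor y₀ is free by default (capturing the
immediate post-bleach level); an anchored-y₀ mode is available. The plateau
bound is 1.5 rather than 1.0 so over-recovery is flagged
(`plateau_at_upper_bound`) instead of silently clamped. Flat traces make
the rate unidentifiable (the exponential term drops out when
plateau = y₀) and are flagged `rate_unidentifiable`. A two-phase model is
deliberately not offered. The rate's 95% CI comes from the asymptotic
standard error and is propagated to a half-time interval
[ln 2/k_hi, ln 2/k_lo].

Derived quantities: stable fraction = 1 − plateau; stable amount = stable
fraction × pre-bleach mean (raw intensity units, comparable only at
identical microscope settings — traces carry a `settings` tag and
mixed-settings aggregation is refused); half-time = ln 2 / k.

Aggregation order is exactly ROIs → wing → group: per wing, mean plateau
and mean pre-bleach combine into a wing stable amount; group mean and SEM
are taken over wings. Group comparison delegates to an unpaired t-test
(two groups) or one-way ANOVA with Tukey's HSD (more), reporting means,
differences and (adjusted) p-values; these are thin contracts over
scipy/statsmodels, not re-implementations.

Re-bleach controls need no bespoke code: the post-second-bleach segment is
fit with `fit_recovery` against its own pre-bleach reference.

## Gradient and internalisation quantification

Per-cell profiles are ordered proximal → distal. The background is the mean
intensity of designated null-clone cells (or a configured scalar); it is
subtracted, the peak cell is normalised to 100%, and the per-cell slope is
100·(v[i+1] − v[i])/v[i] — percent of the more proximal cell. A profile
rising distally (as Fj does) therefore has a positive slope; an exact
geometric profile peak·(1−s)^(distance from distal end) yields
100·s/(1−s) per cell (+3.093% at s = 0.03). A log-linear regression slope
is provided as an alternative metric; the two agree exactly on geometric
profiles. Cells whose corrected intensity is ≤ 0 are flagged, excluded from
slopes, and reported. Replicate profiles are combined as mean-of-replicate
slopes with a t-based 95% CI.

Internalisation courses subtract the laser-off background and normalise to
1.0 at t0; cross-timepoint comparison reuses the ANOVA + Tukey contract.

## Synthetic data

Generators emulate extracted intensity tables, not images, and share one
contract: seeded (`numpy.random.default_rng`), bit-reproducible, truth
record returned alongside the data, and every noiseless output recovered
exactly (≤ 1e−6) by its analysis stage.

- FRAP: exact association curve scaled by the pre-bleach mean, attenuated
  by a constant per-frame multiplicative acquisition-bleach factor
  (1−b)^frame, plus additive Gaussian noise (σ as a fraction of pre-bleach,
  default 2%); matched reference ROIs carry only bleach and noise.
  Defaults follow the canonical stability example (plateau 0.78, rate
  0.02 s⁻¹, pre-bleach 500 → stable amount 110).
- Gradient: geometric decay from a distal peak over 30 cells at 3%/cell
  over a uniform background, clone cells background-only, additive noise.
- Internalisation: geometric retention per 10 min above background.

What the generators do **not** emulate — and hence what passing tests do
not establish about real data: photophysics beyond constant-rate
acquisition bleaching (flicker, z-drift, laser instability), correlated or
intensity-dependent noise, ROI reselection error, biological variability in
rate constants between ROIs of one wing, and any deviation from one-phase
recovery. Parameter-recovery results therefore validate the estimator, not
the acquisition.

## Numerical choices and degenerate inputs

- Steady-state tolerance 1e−9 on the scaled residual; solver tolerances
  1e−10; results are insensitive to the windowing (verified to 1e−6
  against a tighter-tolerance run).
- Zero disfavoured-membrane amounts, terminal-cell asymmetry requests,
  zero total bound in a gradient, non-positive pre-bleach means, t0 at or
  below background, and all-background profiles raise errors rather than
  returning sentinel values.
- Rate constants: k_on > 0 with k_off = 0 is rejected (no irreversible
  binding); slopes are validated against the admissible maximum 1/(n−1).

## Known limitations

- The model is 1D with two membrane compartments per cell; no 2D junction
  geometry, no production/degradation, no feedback amplification or
  cis-clustering, no ongoing kinase/phosphatase kinetics. It predicts
  ~3–10% asymmetries, an order below the ~2-fold Ds asymmetry observed in
  vivo — consistent with downstream amplification being required.
- Absolute rate constants, initial totals and the Fj activity scale are not
  experimentally constrained; only ratios are. Quantitative outputs are
  meaningful relative to the documented calibration point.
- The FRAP pipeline starts from extracted ROI tables and performs no image
  processing; experimental half-time/stable-amount tables from live tissue
  are not reproducible from this package alone.
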