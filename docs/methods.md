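# Methods

This note records the models implemented in `memperm`, their
assumptions, the defaults and why, and what the synthetic-data tests do
and do not demonstrate.

## Free-energy estimation (WHAM)

Each umbrella window i restrains the solute's membrane-normal coordinate
with U_i(z) = ½k_i(z−z_i)². The unbiased distribution is recovered by the
standard single-coordinate WHAM pair

    P(z) = Σ_i n_i(z) / Σ_i N_i exp[(F_i − U_i(z))/k_BT]
    F_i  = −k_BT ln Σ_z P(z) exp[−U_i(z)/k_BT]

iterated from F_i = 0 (log-space, gauge-fixed to F_0 = 0) until the
largest window free-energy change drops below the tolerance. The PMF is
W(z) = −k_BT ln P(z), min-anchored; unvisited bins are masked undefined
rather than zeroed.

Defaults and rationale:

* **Bin width 0.2 Å.** Window spacing is 1 Å and the restrained standard
  deviation at k = 2.5 kcal·mol⁻¹·Å⁻², 310 K is σ = √(k_BT/k) ≈ 0.50 Å,
  so 0.2 Å gives ≥ 2 bins per σ without starving bins of counts.
* **Tolerance 10⁻⁶ kcal/mol on max|ΔF_i|, max 100 000 iterations.**
  Convergence on synthetic data takes a few hundred iterations; the cap
  exists for pathological inputs, which are flagged `converged=False`.
* **Histogram range** spans [min center − 3σ, max center + 3σ] of the
  softest window, covering essentially all restrained density.
* **Duplicate centers** (extra sampling windows at the same z₀) are kept
  as separate windows by default; a pooling mode concatenates them. Both
  give identical PMFs when spring constants match — kept separate so
  per-window diagnostics stay visible.
* Per-bin PMF errors are the Poisson estimate k_BT/√n(z) from total bin
  counts. It ignores time correlation between samples and is therefore a
  lower bound; the asymmetry errors from symmetrization (below) are the
  primary error bars downstream.

Adjacent windows sharing no occupied bins trigger a warning naming the
gap — WHAM cannot bridge disconnected histograms and the relative offset
of the fragments is then arbitrary.

## PMF post-processing

A symmetric bilayer implies an even PMF; `symmetrize` averages W(z) and
W(−z) (linear interpolation for off-grid mirrors) and reports the
half-difference ½|W(z)−W(−z)| as the error bar — sampling asymmetry is
the dominant, honest uncertainty of umbrella PMFs. `anchor_bulk`
subtracts the mean over |z| ≥ 30 Å (both sides pooled), putting the bulk
water plateau at zero. Feature extraction reads the central peak within
|z| ≤ 5 Å and the well within 5 < |z| ≤ 35 Å (overridable); the search
windows bracket the peak at z ≈ 0 and wells anywhere from the interface
(|z| ≈ 14 Å) to the headgroup periphery.

The partition coefficient integrates the Boltzmann factor of the PMF
referenced to the aqueous endpoint(s) over [z₁, z₂] = [−40, 40] Å by
default — the full simulated span; since the integrand is ≈ 1 in bulk,
K is insensitive to modest changes of the bounds. The reference
W(z₁) can be taken from the left endpoint, the right, or their mean
(default mean; identical on symmetrized profiles). Uncertainty is
first-order propagation of per-bin errors treating bins as independent —
an approximation, since WHAM bin errors are correlated; it is reported
as such.

`boltzmann_invert` converts unbiased position samples to
ΔG(z) = −k_BT ln ρ(z) with zero-count bins undefined: a region a
simulation never visited has no measured free energy.

The pKa-shift profile ΔpKa(z) = [ΔW_neutral − ΔW_charged]/(ln10·k_BT)
quantifies where along the membrane normal the neutral form becomes
favored. Both input PMFs must be bulk-anchored; anchoring choices shift
the profile rigidly, which is why anchoring is an explicit, separate
operation rather than folded into WHAM.

## Position-dependent diffusivity

For a harmonically restrained coordinate, D(z_i) = ⟨δz²⟩_i/τ_i, with the
correlation time obtained from the Laplace transform of the position
autocorrelation C(t) = ⟨δz(t)δz(0)⟩:

    τ(s) = Ĉ(s)/C(0),  Ĉ(s) = ∫ e^{−st} C(t) dt,  τ = lim_{s→0} τ(s)

evaluated on the grid s = 0.01…0.1, 0.2…1.0, 2.0…10.0 ps⁻¹ (28 values)
and extrapolated to s = 0 by least-squares fitting a/(s+b) over
s ∈ [0.02, 1.00] ps⁻¹; for a single-exponential ACF the fit is exact
with τ = a/b. The ACF uses the biased (divide-by-N) FFT estimator, and
the Laplace integral is truncated at the first zero-crossing of C(t) or
20 initial e-folding times, whichever is later: beyond that lag the ACF
is statistical noise whose integral corrupts Ĉ(s) precisely at the small
s that dominate the extrapolation. A relative fit residual above 20 %
raises a warning, and a non-decaying ACF (fitted b ≤ 0) is an error.

Window estimates failing these checks are masked in the assembled D(z)
profile, never fatal for the batch; duplicate centers combine by
inverse-variance weights (variance proxy D²/n). Estimator validity
assumes the window samples a locally harmonic region in the overdamped
regime — the same diffusive limit the permeability expression assumes.
No statistical error bars are attached to D(z): the estimator's variance
depends on the ACF tail in a way that simple formulas misstate, and
block-averaging over windows is left to the user.

## Permeability and crossing time

The inhomogeneous solubility–diffusion model gives

    P = [ ∫_{−L/2}^{L/2} exp(W(z)/k_BT)/D(z) dz ]⁻¹

— the reciprocal of the integrated local resistance. Two referencing
conventions are exposed. `border` (default) re-zeroes the PMF so the
mean of W(±L/2) vanishes: appropriate for interfacially bound permeants,
where the relevant barrier is crossing *between* the interfacial wells
(half-widths of 14 Å for a neutral, interfacially bound species and
20 Å for a charged one are typical choices). `bulk` keeps the
bulk-anchored zero — the traditional convention for species with no
interfacial binding. Neither is presumed to generalize; they answer
different kinetic questions.

The crossing time is estimated as τ = L/P with L the integration width.
This is the mean first-passage-style time to traverse the resistive
span, not a rate-theory committor calculation.

Unit handling is centralized: Å²/ps → cm²/s is 10⁻⁴, Å → cm is 10⁻⁸;
D-profile units are resolved from the profile's units tag.

## Ionization

Speciation follows Henderson–Hasselbalch: protonated fraction
1/(1+10^(pH−pKa)). Two apparent→intrinsic conversions are provided:
K_app·10^(pKa−pH) (the customary form, exact when pH ≪ pKa) and
K_app·(1+10^(pKa−pH)) (division by the exact neutral fraction). The
first is the default so published conversions reproduce as printed; the
difference (a factor (1+10^(pH−pKa)), ~11 % one pKa unit above pH) is
documented rather than silently corrected. The deprotonation penalty is
ln10·k_BT·(pKa−pH); at pKa 8.3, pH 7.4 it is 1.28 kcal/mol at 310 K
(1.23 at 298 K — the temperature matters at the 0.05 kcal/mol level).

## Orientation and solvation

Orientation is tracked through a named intramolecular vector (N1 → S
for a sulfonamide drug). The mean angle is the circular mean
atan2(⟨sinθ⟩, ⟨cosθ⟩) — robust for distributions straddling 0°/180° —
and alignment is summarized by S = ½(3⟨cos²θ⟩−1) ∈ [−0.5, 1].

Solvation counts use a nearest-contact rule: an oxygen counts if its
minimum-image distance to *any* solute heavy atom is ≤ 4.25 Å, each
oxygen once per frame. The rule (rather than a center-of-mass distance)
matches how first-shell coordination is defined from site–site RDFs, and
the default cutoff is the canonical first-minimum value for
water/phosphate/ester oxygens around drug heavy atoms. The companion
RDF is, accordingly, a *minimum-site-distance* RDF by default (each
oxygen binned at its distance to the nearest solute atom, shell-volume
normalized to the class's ideal-gas density); a conventional all-pairs
mode exists behind a flag. Cutoffs and r_max beyond half the smallest
box length are rejected (minimum-image violation). Distances are
delegated to MDAnalysis when installed, with a numpy orthorhombic
fallback.

## Synthetic data generator

The generator replaces MD trajectories with overdamped Langevin
(Euler–Maruyama) dynamics on analytic landscapes:

    z ← z + [D(z)/k_BT]·F(z)·dt + D′(z)·dt + √(2 D(z) dt)·ξ

with F = −d(W+U_bias)/dz from a finely tabulated landscape (0.02 Å,
central differences). Overdamped dynamics is the right stand-in because
every downstream estimator assumes the diffusive regime; no velocities
are needed. The spurious-drift term D′(z)·dt is required for a
position-dependent D to leave exp(−W_tot/k_BT) stationary — without it
the stationary density tilts to exp(−W/k_BT)/D(z), a property checked by
a dedicated drift-toggle test.

The membrane landscape is a sum of Gaussians: a central barrier
(default 5.4 kcal/mol, σ = 4 Å), wells at ±14 Å (default −2.8 kcal/mol,
σ = 3 Å), zero in bulk; D(z) crosses over logistically (at |z| = 15 Å,
width 2 Å) from 0.1 Å²/ps in bulk to a 10-fold lower core value. The
default study layout is 81 windows every 1 Å over −40…40 Å at
k = 2.5 kcal·mol⁻¹·Å⁻² and 310 K. Integration uses dt = 0.05 ps with
every 20th point saved (1 ps saved spacing — the readers infer spacing
rather than assume it); a precondition dt < 0.1·k_BT/(k_tot·D_max)
guards the harmonic-relaxation resolution, and 4 000 burn-in steps
(200 ps, many relaxation times of the stiffest window) precede saving.
Window i uses seed base_seed + i, so any window reproduces bit-exactly
in isolation.

What the generator emulates: restrained diffusive sampling on a
membrane-shaped free-energy surface with realistic window spacing,
spring constant and sampling density. What it does not: slow orthogonal
degrees of freedom (drug reorientation, membrane deformation, lipid
rearrangement) that dominate the sampling error of real umbrella
simulations, force-field error, and finite-size/PBC artifacts. Passing
recovery tests therefore demonstrates the *estimators* are correct and
well-conditioned at realistic data sizes — not that any particular MD
study is converged.

## Problem sizes and numerical choices

Recovery tests run at the study's own scale: 81 windows × 5×10⁴ saved
points for the full pipeline (PMF RMSD < 0.15 kcal/mol, barrier error
< 0.3 kcal/mol, permeability within 25 % of the analytic resistance
integral on the generating truth); unit tests use smaller window sets
chosen so each check's statistical power comfortably exceeds its
tolerance. All stochastic tests are seed-pinned. Quadrature is
trapezoidal throughout (exact for the flat-profile limits K = 1 and
P·L/D = 1); interpolation is linear with no extrapolation — undefined
beyond or between defined data. Degenerate inputs (empty histograms,
constant series, zero-length orientation vectors, disjoint grids) raise
errors naming the offending window, frame or gap rather than producing
numbers.

## Known limitations

* WHAM bin errors and the independent-bin error propagation understate
  correlated uncertainty; asymmetry error bars are the primary estimate.
* Single reaction coordinate only: no 2-D umbrella sampling, no MBAR
  (an independent maximum-likelihood solve appears in the tests as a
  cross-check oracle), no reweighting across temperatures.
* The permeability model is the 1-D solubility–diffusion integral; it
  ignores interfacial (de)binding kinetics and lateral heterogeneity.
* The generator's constant-tilt unbiased mode is a crude stand-in for a
  time-ramped transmembrane field and is not presumed equivalent.
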