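# Methods

## Scope and model system

The package analyses Zn(II) binding to classical CCHH zinc fingers: small
ββα peptides that coordinate one Zn(II) through two cysteine thiolates and
two histidine imidazoles. It implements the data analysis only — curve
fitting, speciation, thermodynamic bookkeeping, and trajectory
post-processing. It does not run MD/SMD simulations, model structures, or
control instruments; trajectories, structures, and titration data are
inputs (or synthetic stand-ins).

## Thiol pKa and average protonation

The two cysteine thiols are treated macroscopically: two stepwise acid
dissociations with pK₁ ≤ pK₂ and three absorbance plateaus A₀ (diprotonated),
A₁ (mono), A₂ (thiolate), combined with a statistical factor 2 on the doubly
deprotonated term. The model is fitted by bounded trust-region least squares
(scipy `least_squares`, xtol/ftol/gtol 1e−10, ≤10⁴ evaluations), initialised
from the curve extremes with pK guesses at the 1/3 and 2/3 quantiles of the
pH range; labels are swapped on exit if the optimizer crosses pK₁ > pK₂.
Fits whose pK values fall outside the sampled pH range ± 1 unit are flagged
(`in_range=False`) rather than rejected.

The average proton load is the macroscopic partition-function mean

n_H(pH) = (10^(pK₂−pH) + 2·10^(pK₁+pK₂−2pH)) / (1 + 10^(pK₂−pH) + 10^(pK₁+pK₂−2pH)),

bounded in [0, 2] and monotone nonincreasing in pH. The test suite checks it
against an independent oracle, the numerical derivative −∂lnZ/∂(pH·ln10) of
the binding polynomial, on a 10×10×10 parameter grid.

**Identifiability.** A pK₂ near 8.8 cannot be determined from a titration
that stops at pH 8: the second transition is unsampled and the least-squares
optimum genuinely sits elsewhere (verified: a fit started at the truth moves
away from it). The synthetic generator's default grid is the instrument
window pH 3→8 (step 0.1, 51 points); parameter-recovery tests therefore pass
an explicit pH 3→10 grid that samples through both transitions. This is an
identifiability requirement of the experiment design, not a fitting
tolerance.

## Competition affinity and speciation

The Hill model is implemented with Θ_min paired with xⁿ (signal moves from
Θ_max at zero Zn to Θ_min at saturation). Whether this weighting or its
mirror is used changes only which plateau is called Θ_min; the fitted
half-saturation free Zn(II), and hence K_d, is identical. Fitting is done in
pZn space with zn_half parameterized as −log₁₀ (bounds [0, 25]) for
conditioning across femtomolar–micromolar affinities; n is bounded to
[10⁻³, 10]. A fit is declared unidentifiable when the fitted half-saturation
pZn lies outside the sampled window or the data traverse less than 20% of
the fitted amplitude — the post-fit form is needed because an all-apo series
looks like a valid (tiny) transition when judged against its own data range.
Replicate kinetic reads are averaged per point before fitting
(`CompetitionSeries.from_replicates`).

Free Zn(II) in a chelator metal buffer is computed with the standard
conditional-constant treatment at fixed pH: protonation equilibria are
folded into α_H(L) = 1 + Σᵢ 10^(ΣlogKⱼ − i·pH), the optional ZnHL ternary
complex into β′ = (β_ZnL + β_ZnHL·10^(−pH))/α_H(L), and the two mass
balances are solved by damped Newton iteration on (log[Zn], log[L′])
(half-stepping on residual increase, start from the excess-ligand closed
form, convergence at 10⁻¹² relative residual, hard stop at 200 iterations).
Log-variables guarantee positivity across the ~10 orders of magnitude of
free Zn this chemistry spans. Species are restricted to L/HL…HₙL, ZnL,
optional ZnHL, and free Zn: the buffers modelled here avoid hydroxide and
polynuclear chemistry, and a general N-component speciation engine is out of
scope. The peptide correction subtracts saturation·[peptide] from total Zn
and re-solves; when a peptide K_d is supplied, saturation = z/(z + K_d) is
iterated to a fixed point (|ΔpZn| < 10⁻⁶, typically < 10 iterations).

Chelator constants (EDTA, EGTA, HEDTA, TPEN, NDAP, EDDS) ship as a YAML
registry with per-record literature notes; they are parameterization, not
algorithm, and users can point every entry point at their own file. No
ionic-strength or temperature corrections are applied — constants are taken
as conditional at the stated medium. The NDAP and EDDS entries are
representative rather than critically evaluated and are so labelled.

## ITC model and enthalpy decomposition

The forward isotherm is the single-site equilibrium per injection with exact
volume-displacement bookkeeping: the cell volume is constant, each injection
expels liquid of pre-injection composition (diluting both cell species by
1 − dV/V₀), and the heat of injection i is ΔH times the net change of bound
complex in the cell. Bound complex comes from the closed-form quadratic; the
test oracle recomputes it by bracketing root-finding on free titrant.
Heats are in µcal, enthalpies in kcal/mol (1 kcal = 10⁹ µcal). The fit
estimates (n, log₁₀K_b, ΔH_ITC, dilution offset) by bounded least squares
(n ∈ (0, 2], log₁₀K_b ∈ [2, 15]); a saturation flag is raised when the final
molar ratio is below 1.2·n. The default design is 25 × 6.82 µL injections of
0.35 mM Zn(II) into 1 mL of 30 µM peptide at 298.15 K in HEPES.

The decomposition chain uses the buffer correction
ΔH° = ΔH_ITC + n_H·ΔH°_buff with ΔH°_buff(HEPES) = +5.02 kcal/mol: the
protons released by the thiols protonate the buffer, and that exothermic
contribution is removed from the observed heat. (Writing the correction with
a minus sign instead would make the corrected enthalpies more exothermic
than the observed ones, which contradicts the proton-release chemistry and
the published ledgers this chain reproduces; the plus convention is used
throughout.) The remaining steps are exact arithmetic:
ΔH_CysH = n_H·8.5, ΔH_Zn-pep = ΔH° − ΔH_CysH,
ΔH_folding = ΔH_Zn-pep − [(4 − n_His)(−5.0) + n_His(−5.0)],
ΔG° = −(ln10)·R·T·(−logK_d), −TΔS° = ΔG° − ΔH°. Every produced ledger
satisfies the three identities to machine precision; `validate_ledger`
re-checks them at a 0.05 kcal/mol tolerance chosen to absorb the rounding of
two-decimal published entries, and will flag externally supplied rows whose
cells are mutually inconsistent beyond that.

## Steered-MD post-analysis

Contact numbers use the rational switching function with n = 8, m = 12,
r₀ = 2.8 Å; the removable singularity at r = r₀ is evaluated as its limit
n/m, and |r/r₀ − 1| < 10⁻⁷ is mapped to that limit to keep the evaluation
stable. The far tail decays as (r/r₀)^(n−m) = (r/r₀)⁻⁴ — slow, which is why
release detection uses a threshold rather than waiting for CN ≈ 0. His
ligands are represented by their coordinating N atom and Cys by Sγ, one atom
per ligand, so each ligand's CN runs from ≈1 (bound) to ≈0.

A ligand is released at the first frame after which its CN stays below 0.5
for at least 50 consecutive frames; shorter excursions count as transient
rebinding. Both threshold and persistence are exposed as parameters since
the event criterion is a modelling choice. Ligands below threshold at frame
0 are flagged pre-dissociated. Release events ordered by frame give the
pathway signature and the ZnL₄→ZnL₀ intermediate labels; a census over
replicas reports per-signature counts and fractions (summing to 1).

Rupture statistics report both interpretations of "rupture force": the
per-event maximum pulling force in the window since the preceding release,
keyed by ligand and by ZnL level, and the per-replica global maximum; the
replica-set mean is the arithmetic mean of the global maxima. Work is the
trapezoidal integral of force over the reaction coordinate (kcal/mol with
force in kcal·mol⁻¹·Å⁻¹; no pN conversion is attempted).

Hydrogen bonds use a heavy-atom donor–acceptor distance < 3.0 Å and a
deviation of the D–H⋯A axis from linearity < 20° (computed as 180° minus
the D–H–A angle at the hydrogen). A literal D–H–A angle below 20° is
geometrically impossible at a 3 Å contact, so the criterion is necessarily
the deviation form; both cutoffs are configurable. RMSD offers optional
optimal rigid-body superposition (Kabsch, via scipy's rotation alignment);
RMSF is taken about the mean structure. The FES is −RT·ln(p/p_max) over a
2-D histogram of projected samples (≥100 required), with empty cells at +∞
and grid-local minima reported; PCA projection itself is standard plumbing
left to the caller.

## Synthetic data: what it does and does not emulate

Generators are deterministic under a fixed seed (numpy `default_rng`) and
return their ground truth alongside the data. Noise models: additive
Gaussian for absorbance (default sd 0.002 AU) and ellipticity (1% of signal
range); heat noise proportional to |heat| with a 0.1 µcal floor, emulating
integration error on small tail peaks; coordinate jitter uniform in a sphere
(0.05 Å default, far below the persistence tolerance). Ground-truth defaults
sit in the regime the analysis targets: −logK_d 12.3–14.5, ΔH_ITC −17 to
−21 kcal/mol, n_H 1.5–1.7, thiol pK near 7.6/8.8. The SMD generator scripts
the release order with a 10-frame distance ramp and a triangular force peak
per event over a 700-frame run.

These generators reproduce the signal shapes and noise magnitudes, not the
physics: there is no wavelength structure, no baseline drift or injection
artefacts, no real protein geometry beyond the five metal-site atoms, and
scripted (not emergent) rupture events. Passing recovery tests therefore
demonstrates that the estimators are correct and unbiased for the stated
models at realistic conditioning — not that the models capture every feature
of real instrument output.

## Problem sizes and numerical policy

Test problem sizes are the experiments' own: 51–71-point titrations,
19-point competition series, 25-injection isotherms, 40–50 replica
trajectories of 700 frames. Recovery bias is assessed over 50 seeds with a
2-standard-error criterion. The speciation solver is verified against a
bracketing root-finder to 10⁻¹⁰ relative free-Zn error over 100 random
buffers; the ITC forward model against a per-injection equilibrium
root-solve to 10⁻⁸ relative.

## Known limitations

- Speciation handles one chelator + Zn (+ one peptide); no multi-metal or
  multi-ligand systems, no hydroxo/polynuclear species.
- The ITC model is single-site; no multi-site or displacement titrations,
  and no raw-thermogram baseline integration (inputs are integrated heats).
- pKa analysis is single-wavelength; no global spectral fitting.
- H-bond detection is geometric only (no energetic or topological criteria)
  and requires explicit hydrogens mapped to donors.
- Published thermodynamic-ledger reproduction is bounded by the two-decimal
  rounding of the published inputs (≈0.05 kcal/mol propagated).
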