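# Methods

## The kinetic model

Trypsin-fold proteases pre-exist in two active-site conformations: a closed
form E\* that cannot accept ligand and an open, binding-competent form E.
Ligand binding therefore follows conformational selection,

    E*  ⇌(k12/k21)  E  +  L  ⇌(kon[L]/koff)  E:L

with first-order interconversion rates `k12` (opening) and `k21` (closing),
a second-order association rate `kon` and dissociation rate `koff`.  Under
pseudo-first-order conditions ([L] ≫ [P]) the linearised scheme relaxes to
equilibrium bi-exponentially with rates

    2·α(1,2) = k12 + k21 + kon[L] + koff
               ± sqrt((kon[L] + koff − k12 − k21)² + 4·k21·kon[L]).

The fast root α₁ reports mainly on binding and grows without bound in [L];
the slow root α₂ always saturates: α₂(0) = koff (for koff < k12 + k21) and
α₂(∞) = k12, and the profile rises, falls or stays flat according to the
sign of k12 − koff.  The saturable α₂([L]) is the signature separating
conformational selection from rigid lock-and-key binding, whose single
relaxation α = koff + kon[L] is a straight line.  Two derived quantities
summarise the free-protein equilibrium: the interconversion time scale
τ = 1/(k12 + k21) and the population ratio E\*:E = k21/k12.

Numerically, α₁ is computed from the (cancellation-free) plus root and α₂
from the product identity α₁α₂ = koff(k12 + k21) + k12·kon[L], which is
stable at large [L] where the naive minus root loses precision.

Each rate constant carries an Arrhenius temperature law
`k(T) = k0·exp(−(Ea/R)(1/T − 1/T0))` with `Ea` in kcal/mol,
R = 1.987 cal mol⁻¹ K⁻¹ and reference temperature T0 = 288.15 K (15 °C),
the convention the stopped-flow constants are quoted in.  Evaluating at
T = T0 returns `k0` exactly.

## Synthetic data generator

`cskinetics.simulate` integrates the full second-order mass-action
equations (scipy BDF with analytic Jacobian, rtol 1e−10, atol 1e−12 μM) —
no pseudo-first-order shortcut — starting from the free protein at its
conformational pre-equilibrium (E\*:E = k21:k12) with ligand mixed in at
t = 0.  Totals of protein and ligand are conserved to better than 1e−9
relative.  The induced-fit alternative (binding first, isomerisation
second) is implemented with the same machinery for mechanism
discrimination.

The observation model emulates a fluorescence stopped-flow instrument:

* signal = weighted sum of species concentrations.  The default weights
  make the closed E\* conformation spectroscopically distinct with open
  protein and complex equal, so the signal tracks the conformational
  population and the fast binding relaxation is effectively silent — the
  regime reported for PPACK binding to thrombin, where only the slow
  relaxation is detectable.  A binding-sensitive observable (complex
  brightest, both relaxations visible) is available as a config switch and
  is used automatically for frozen-conformation (lock-and-key) variants
  and for the excess-macromolecule diagnostic, where binding is the only
  signal there is.
* dead time 1 ms by default (upper end of the 0.5–1 ms instrument range);
  samples before it are discarded.
* homoscedastic Gaussian noise with s.d. = 5% of the trace dynamic range
  by default, applied per replicate; 10 replicates are averaged per
  recorded trace, as in the experimental protocol.
* time grids are logarithmic; when not supplied they span half the dead
  time to six expected slow time constants (clamped to 0.1–100 s), so both
  relaxations are sampled for fast variants and slow lock-and-key mutants
  alike.

Default titration design: 8 ligand concentrations, 2.5–70 μM, against
0.15 μM protein (the study's concentration range), temperatures 5–30 °C
for temperature series; the excess-macromolecule regime enforces
[P]/[L] ≥ 10 as the excess-ligand regime enforces [L]/[P] ≥ 10.

What the generator does *not* model: photophysics of individual
fluorophores, instrument artifacts beyond dead time and Gaussian noise,
baseline drift, and the slow covalent acylation chemistry of
chloromethylketone ligands.  Passing recovery tests therefore demonstrate
correctness of the inference machinery under the stated noise model, not
robustness to every pathology of real instruments.

A note on pseudo-first-order accuracy: an irreversible ligand is depleted
by one protein equivalent over the course of binding, so at [L]/[P] = 50
the extracted noise-free rate matches the closed form evaluated at the
mean free-ligand concentration [L] − [P]/2 (to 1%), not at the nominal
[L]; the discrepancy vanishes as the excess grows.

## Exponential extraction

Traces are fit to `b + Σ aᵢ·exp(−rᵢ t)` (one or two components) by
variable projection: amplitudes and baseline are solved linearly at each
trial rate vector, and only the log-rates are optimised nonlinearly, from
8 log-spaced multi-starts spanning the observable window.  The baseline is
always fitted (mixing offsets are unavoidable in real data).

Model selection mirrors "analysis of residuals" conservatively: the second
exponential is accepted only when it improves small-sample AICc by more
than 10 **and** the one-exponential residuals fail a Wald–Wolfowitz runs
test at α = 0.05 (both thresholds config-exposed).  Rates at the grid
Nyquist bound, or slow rates whose time constant exceeds a third of the
record, are flagged rather than silently trusted.  Relaxations faster than
the dead time are not deconvolved; they are simply unresolved, as in the
experiment.

Replicate fits at one design point are combined by majority rule on the
component count (disagreements flagged); per-point errors come from the
replicate spread when ≥ 3 independent fits exist, else from the fit
covariance.  A single observed relaxation is labelled "slow", the
saturable relaxation followed in titrations.

## Fitting and mechanism discrimination

Titration fits are weighted least squares (weights 1/σ², uniform when
errors are absent) with bounded multi-start optimisation (16 log-uniform
starts; near-ties resolved toward the smaller k21).

A single-temperature α₂ profile determines the asymptote k12 and the
initial slope kon·k12/(k12+k21) well, but leaves k21 and kon trading along
a ridge.  The conformational-selection fit therefore fixes koff (0 for
irreversible ligands) and constrains kon to an independently known
interval (default 0.5–3 μM⁻¹ s⁻¹, bracketing the wild-type association
rate; always user-overridable and recorded in the output).  A profile scan
over k21 documents the selected local minimum.  Identifiability is judged
from the profile: if the ~95% region (objective within 3.84 of the
minimum, the one-parameter chi-square quantile) touches the scan bounds or
spans more than a decade, the fit is flagged `k21_weakly_identified`
instead of silently reporting a point estimate.  Standard errors come from
the Jacobian at the optimum; the profile scan is the authoritative
uncertainty statement when the two disagree.

Mechanism classification compares the lock-and-key line with the
conformational-selection expression: the hyperbolic model is accepted only
when it wins AICc by > 10 *and* the data genuinely curve (the fitted
initial-slope extrapolation at the top ligand concentration exceeds the
fitted k12 asymptote, i.e. the titration reaches saturation); truly linear
data default to the simpler lock-and-key model provided its residuals pass
the runs test; datasets too small for the small-sample criteria return
"indeterminate".

The temperature-global fit expresses k12, k21 and kon through their
Arrhenius laws ({k0, Ea} each, koff fixed) and runs one weighted objective
over all (T, [L]) observations.  Because binding and conformational
exchange have different activation energies, their contributions decouple
across temperature and all six parameters become identifiable without the
kon constraint — the fit refuses to run with fewer than 3 temperatures or
4 ligand points per temperature.

The excess-macromolecule diagnostic extracts the observed relaxation as a
function of protein concentration and tests linearity against a saturating
hyperbola: conformational selection predicts a straight line with slope
kon × (open fraction); induced fit stays hyperbolic.  The hyperbolic
verdict requires an AICc win > 10 with the fitted half-saturation inside
(< 3× of) the sampled range; at least four protein concentrations are
required.

## Structural gauge

The Cα(G193)–Cα(G216) distance (chymotrypsin numbering) measures the
aperture to the primary specificity pocket and is bimodal across deposited
trypsin-fold structures, with modes near 8.3 Å (E\*) and 12.2 Å (E).  The
classifier thresholds, 9.5 Å and 11.0 Å, are this package's quantisation
of that bimodal description (the literature gives peaks, not boundaries)
and are config-exposed.  Alternate locations resolve to the
highest-occupancy Cα; each model of a multi-model file is reported
separately; a chain missing either residue yields a per-chain error
without aborting the file.  A numbering map supports proteases deposited
with non-chymotrypsin numbering.

## Problem sizes and reproducibility

Recovery studies in the test suite use the study-scale designs: 8-point
titrations (2.5–70 μM) for single-temperature fits, 6 × 8 (temperature ×
ligand) for the global fit, 12 protein concentrations (1–20 μM) for the
excess-macromolecule diagnostic, traces of 600 log-spaced samples.  All
stochastic steps take explicit seeds; per-trace noise streams are spawned
from one base seed, so whole titrations are reproducible and traces are
mutually independent.  Induced-fit comparison simulations use
kon = 3 μM⁻¹ s⁻¹, koff = 5 s⁻¹, kf = 15 s⁻¹, kr = 2 s⁻¹, chosen so the
half-saturation of the slow relaxation (~6.7 μM) lies inside the sampled
protein range — a discrimination test against an alternative whose
curvature cannot be sampled would be vacuous.

## Design choices and known limitations

* Configuration validation uses dataclass invariant checks plus CLI-level
  schema checks (unknown config fields are rejected by name); no external
  validation framework is required.
* Rates are kept in μM⁻¹ s⁻¹ / s⁻¹ internally; M⁻¹ s⁻¹ is accepted at the
  fold-change interface with explicit units.  Mixing first- and
  second-order rates is a dimensional error, not a warning.
* The E\*:E ratio is rendered `n:1`/`1:n` by rounding the larger/smaller
  quotient to the nearest integer, the field's presentation convention.
* Amplitude conventions are synthetic-only: the observable weights are an
  instrument model, and no claim is made that they reproduce real
  fluorescence yields.
* The two-stage workflow (extract rates, then fit profiles) mirrors
  experimental practice; raw traces are never fit directly to the ODE.
* For τ of the inactive S195A variant the package computes 51 ms from the
  published rate constants (16 + 3.8 s⁻¹); a 56 ms figure circulating in
  prose is inconsistent with those constants and is not reproduced.
* The printed excess-macromolecule slope (2.1 μM⁻¹ s⁻¹) exceeds
  kon × (open fraction) computed from the published constants (≈ 1.3);
  only the linearity property, not that slope value, is asserted
  quantitatively.
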