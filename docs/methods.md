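# Methods

This note documents the models implemented in fuzzbind, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the known limitations.

## Charge bookkeeping

Protein charges use the integer convention appropriate near pH 7.5: Arg/Lys
+1, Asp/Glu −1, His 0 (His pKa ≈ 6), termini uncharged. RNA carries −1 per
nucleotide — a bookkeeping convention that counts one formal charge per
phosphodiester unit including the 5′ end, so an N-mer is −N. Both
conventions are what the coacervation stoichiometry arguments assume; a
pH-aware override hook (`charge_fn`) lets users substitute fractional
charges. NCPR profiles use a centered window (default 5, odd) truncated at
the termini so the profile length always equals the sequence length.

## Binding models and fitting

The 1:1 model solves the mass balance exactly (quadratic in the complex
concentration) rather than assuming excess titrant; this is costless and
correct at any probe concentration. The 2:1 model is two sequential
macroscopic equilibria P+R ⇌ PR (K1), P+PR ⇌ P2R (K2) solved by bracketed
root-finding on free protein, with a single shared bound-state anisotropy by
default and per-species endpoints as an option.

Fitting is least squares with K_D parameterized on the log scale to enforce
positivity. Initial guesses: r_free from the first point, r_bound from the
last, K_D from the median titrant concentration — robust for
sigmoid-in-log-concentration data. When per-point replicate SDs are present
they are used as weights **after variance moderation**: per-point variances
are shrunk halfway toward the pooled variance before inverting. Raw 1/s
weights from three replicates are statistically pathological (the sample SD
of n=3 is chi-distributed with 2 df, and an occasional near-zero SD would
dominate the fit); moderation restores nominal ~95% interval coverage in the
seeded recovery studies run by the test suite. Confidence intervals come
from the linearized covariance with a t critical value; a seeded residual
bootstrap is available. Model comparison uses AICc with ties flagged at
|ΔAICc| < 2.

## Coarse-grained simulator

One bead per amino acid or ribonucleotide. The short-range pair term is the
Wang–Frenkel potential with cutoff 3σ (it vanishes smoothly there, so no
shifting is needed), pair parameters by Lorentz–Berthelot-style combination;
electrostatics are Debye–Hückel with the Bjerrum length from temperature and
dielectric and the screening length from ionic strength, truncated and
shifted at the nonbonded cutoff. **The bundled parameter table is a
synthetic, package-authored parameterization** built from standard residue
masses/sizes and interaction-class reasoning (aromatics > aliphatics >
polar, Arg cation-π-capable, stacking-capable nucleotides, ±0.75 e scaled
charges on ionizable groups and nucleotides); it is in the style of
residue-resolution IDP/RNA force fields but is not a transcription of any
published set, and quantitative observables (relative affinities in
particular) inherit that uncertainty.

Dynamics are BAOAB Langevin. Flexible chains are bead-spring polymers
(k = 8000 kJ/mol/nm², rest length 0.381 nm for Cα–Cα and 0.50 nm for P–P
virtual bonds; directly bonded pairs excluded from nonbonded terms). A
folded RNA conformer is a rigid body: translational Langevin on the center
of mass plus the Euler equations (gyroscopic term included) in the principal
frame, with an Ornstein–Uhlenbeck thermostat on the body-frame angular
velocity and quaternion orientation updates. Initial configurations use an
overlap-avoiding random walk followed by capped-displacement steepest
descent, and the first 10% of steps are discarded as equilibration.
Defaults: 25 nm box, 300 K, 150 mM, dielectric 80, 10 fs timestep, friction
0.01/ps — standard for this force-field class; the weak friction accelerates
diffusive exploration, and tests that thermometer the integrator use
stronger coupling (1/ps) so the kinetic temperature estimator converges.
Runs are bitwise reproducible given (topology, config, conformer).

Multi-conformer rigid RNA is handled by pooling separate runs per conformer
(each with a derived seed); a conformer-swap Monte Carlo mode is also
provided that exchanges the rigid coordinates every `swap_every` steps after
least-squares superposition onto the current pose, with a Metropolis test on
the potential-energy change and angular-momentum resampling on acceptance.

Bound-state classification: a frame is bound when at least `min_contacts`
interchain bead pairs (default 1) are within the cutoff, which defaults to
1.2× the mean pair contact distance. With one molecule of each species in a
box of volume V, K_D,app = (1 − f_b)²/(f_b·V·N_A); the ratio between two
RNAs at matched boxes is volume-independent.

### Relative-affinity study conditions

The two-chain study (structured TAR-like hairpin vs homopolymer rU29) uses a
12 nm box, 800 mM ionic strength, 100k production steps saved every 500, and
pools three toy conformers (or three seeds for the flexible RNA). The salt
was fixed by a pre-registered criterion — the lowest value in the scan
{150, 400, 600, 800} mM at which **both** systems show binding *and*
unbinding events, since the mass-action estimator needs 0 < f_b < 1 — before
any affinity ratio was computed.

## Ensemble observables

Coordinates are Å in this layer (nm in the simulator; converters at the
boundary). Per-frame Rg is about the unweighted site centroid; KDE
densities use Gaussian kernels with Scott bandwidth and integrate to 1.

The random-coil null model is an ideal chain with exponent 0.5: rms
inter-residue distance b√|i−j|, mean distance with the Maxwell factor
√(8/3π), closed-form rms Rg b√((N²−1)/6N). The effective bond length
b = 6.18 Å is calibrated once so the 68-residue chain gives the 20.8 Å
random-coil reference Rg; `AFRCReference.sample` draws ensembles with the
model's own (Gaussian-bond) statistics for self-consistency tests.
Normalized distance maps divide observed mean distances by the null model's
mean distance at the same separation (diagonal masked).

PRE: Γ₂(i) = K·τ_c·⟨r_i⁻⁶⟩ with the ensemble average over frames, intensity
ratio R₂·exp(−Γ₂·t_d)/(R₂+Γ₂) ∈ [0,1]; defaults τ_c = 4 ns, K = 1.23×10¹⁶
Å⁶s⁻² (standard nitroxide–¹H constant), R₂ = 10 s⁻¹, t_d = 10 ms, all
exposed. The label site reports 0 by convention. Note that ⟨r⁻⁶⟩ averaging
on non-self-avoiding model chains is dominated by rare close approaches;
basin-shape intuition applies to chains with excluded volume.

Helicity is a dihedral criterion (φ ∈ [−100°,−30°], ψ ∈ [−80°,−5°], runs of
≥3 residues), a deliberate substitute for chemical-shift back-calculation,
not an equivalent. Secondary-structure propensity is the windowed
ΔδCα − ΔδCβ scaled by a 2.8 ppm full-helix reference, symmetric for
positive/negative propensities so the profile is antisymmetric under
secondary-shift sign flips. CSP combines per-nucleus weighted shifts
(weights ¹H 1.0, ¹⁵N 0.154, ¹³C 0.25, overridable) as the root mean square;
a max-¹³C variant reports the largest single carbon |Δδ|, supporting both
sugar and base carbons.

Scattering uses the orientationally averaged Debye sum with unit point form
factors (I(0) = N²) — a reduced representation without atomic form factors,
hydration layers or excluded-volume corrections, adequate for
Guinier/Kratky-level shape analysis of the model ensembles. Guinier fits
ln I vs q², iteratively shrinking the range until q_max·Rg ≤ 1.3.

## Phase analysis

Turbidity is an arbitrary-units order parameter (no scattering physics).
Features come from a 3-point moving average: argmax for the peak, plateau
flagged when the last three points are within noise of the maximum, onset at
baseline + 3 SD. Salt series are sorted internally and report a strict
monotone-decrease verdict plus the linearly interpolated half-decay
midpoint. Phase diagrams threshold mean turbidity at baseline + 5·SD by
default and report linear threshold crossings along rows and columns as the
boundary.

## Synthetic generators

Every generator is a pure function of (parameters, seed); a master seed
spawns one independent stream per generator, and a TruthRecord (JSON)
accompanies each dataset. Defaults are the study conditions: 16-point
log-spaced titrations of a 10 nM probe up to 20 µM titrant with σ_r = 0.002
and 3 replicates; chains with 3.8 Å bonds and an ideal-helix segment
(1.5 Å rise, 2.3 Å radius, 100°/residue) present in a tunable fraction of
frames; hairpin conformers as two A-form-like rods (2.8 Å rise, 9 Å radius,
32.7°/nt) meeting at a 52° interhelical angle with Gaussian jitter;
turbidity as a log-normal bump (optionally saturating) peaking at the
charge-matched ratio 29/12. The chains are freely jointed (a Gaussian-bond
option reproduces ideal-chain statistics exactly, which the null-model
closure tests use); none of the generators emulate excluded volume,
sequence-specific RNA thermodynamics, or real all-atom geometry, so passing
closure tests demonstrates correctness of the analysis code, not realism of
the ensembles.

## Known limitations

* The force-field table is authored, not transcribed; relative affinities
  from it are directional statements at best. In the pooled study the
  structured hairpin binds far tighter than rU29 (K_D ratio ≫ 1), but the
  magnitude is much larger than the ~3.5-fold seen experimentally, partly
  because (1 − f_b)²/f_b amplifies differences at extreme bound fractions.
* At the study conditions the protein *extends* along the RNA on binding
  (adsorption on a rod-like polyanion) rather than compacting; reproducing
  binding-induced compaction evidently requires stronger short-range
  protein–RNA cohesion and/or a more compact RNA geometry than the toy
  hairpin provides. The acceptance suite asserts the compaction direction
  and reports this failure rather than hiding it.
* The 2:1 isotherm model is one reasonable parameterization of sequential
  binding, not a unique one; it serves as an alternative hypothesis for
  model comparison.
* Rigid-body Langevin sampling uses a splitting scheme that is approximate
  for rotational degrees of freedom at large timestep × torque; for the
  binding statistics collected here the translational/orientational
  diffusion it produces is adequate, and the kinetic temperature of mixed
  systems stays within a few percent of the set point.
* Simulation problem sizes in the test suite (10–97 beads, 10⁴–2×10⁵ steps,
  2–6 pooled runs) are chosen so the whole suite runs on a laptop-scale
  single core in about a minute while still containing multiple
  binding/unbinding events; production studies should scale n_steps and the
  conformer pool up by one to two orders of magnitude.
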