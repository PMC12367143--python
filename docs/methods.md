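# Methods

## Reaction schemes

Aminoacylation is modelled as a graph of enzyme states connected by
reversible elementary steps.  Each state records the ligand content of
each catalytic site (codes: T = ATP, M = AMP, P = PPi, A = amino acid,
D = aminoacyl-adenylate, R = tRNA, R* = aa-tRNA); a site holds at most
one of {R, R*} and at most one of {T, M, D}.  Conformational substates
and editing/proofreading reactions are outside the model's scope.

The class I monomer scheme has 16 states (S0–S15) and 24 reversible
steps (48 rate constants):

* random binding of amino acid, ATP and tRNA (tRNA binds every tRNA-free
  state except the transient adenylate·PPi complex S4);
* activation (A + T → D + P on the enzyme) from the ternary substrate
  complex, with or without tRNA bound.  For argRS, gluRS and glnRS the
  tRNA-free activation step is absent;
* two orders of PPi release relative to transfer — PPi can leave before
  (S10→S11→S13) or after (S10→S12→S13) the amino acid moves onto the
  tRNA.  Without the second path the fitted Km values for ATP and amino
  acid in the aminoacylation assay come out far too low;
* a product-release fork: the charged tRNA can leave directly
  (S14→S0), or ATP can bind first (S14→S15) so that ATP competes with
  AMP for the product-bound enzyme and drives release.  Releasing the
  product from S15 leaves the ATP-bound enzyme (S2), which re-enters the
  cycle.

The pyrophosphate-exchange subscheme is the restriction to the six
tRNA-free states (12 rate constants); the single-turnover subscheme is
the induced subgraph on {S0, S5, S11, S13, S14} (8 rate constants,
starting from the isolated enzyme–adenylate complex).  Both are
literally subgraphs of the full scheme, so parameters constrained by
those assays carry over unchanged.

Class II enzymes (and the class I dimer metRS) use a half-of-sites
"flip-flop" extension: the class I chemistry runs in site 1, the charged
tRNA stays bound while amino acid and ATP bind and activate in site 2,
and only after that second activation is the site-1 product released
(from the site-2 adenylate states, with or without PPi still bound).
On release the dimer "flips": the site-2 adenylate becomes the new
site-1 species.  Site 2 is modelled without a tRNA of its own — product
release is permitted regardless of tRNA occupancy at site 2, and the
next tRNA is recruited after the flip.  The dimer counts as two sites
in the burst-amplitude normalization.

## Units and conditions

Time in s, concentrations in µM, bimolecular rate constants in
µM⁻¹s⁻¹, volumes in litres; 1 µM corresponds to 602.214 molecules per
µm³ (6.02214e17 per litre).  Default assay conditions follow standard
protocols: pyrophosphate exchange at [PPi] = 2 mM, [ATP] = 5 mM,
[AA] = 0.5 mM, [E] = 10 nM; aminoacylation adds [tRNA] = 10 µM; single
turnover uses [tRNA] = 5 µM with [E] = 50 µM (ten-fold excess); the
pre-steady-state (burst) assay uses [E] = 0.25 µM.  Where a protocol
states a range ([AA] = 0.5–1 mM, [E] = 1–10 nM) the defaults sit at
0.5 mM and 10 nM.

## Simulation

Abundant substrates (ATP, amino acid, PPi, AMP) are constant-
concentration baths by default, making their binding steps
pseudo-first-order; tRNA and aa-tRNA may be tracked as discrete counts
(they are depleted in single-turnover and demand simulations).  The
simulation volume is derived from the enzyme copy number (default 50 to
a few hundred copies for velocity assays, chosen so velocity estimates
have enough events) rather than from the nominal assay volume; with
baths this changes only the noise, not any mean.

Three solvers share one compiled reaction table: the exact Gillespie
direct method (numba-jitted, full propensity recomputation per event,
fixed output grid of duration/500 by default), mean-field ODE
integration (scipy LSODA), and the exact stationary distribution of the
enzyme-state chain under constant pools (a linear solve), which equals
the mean-field steady state and is used wherever a deterministic
velocity is wanted.  Product formation is counted as net transfer
firings; the exchange observable counts one-way reverse-activation
firings (the labelled-ATP flux equals this count times the specific
activity s(0), so counting firings is an equivalent, lower-variance
measurement than tracking labelled molecules explicitly).

Initial velocities are slopes of cumulative counts over a window that
ends when 5% of the limiting depletable pool is consumed (the whole run
when everything is a bath); the first 30% of that window is discarded so
the pre-steady-state transient (burst or lag) does not bias the
steady-phase slope.

## Estimators

**Woolf–Hanes.** Unweighted ordinary least squares on ([S], [S]/v);
kcat = 1/slope, Km = intercept/slope, exact on noiseless MM data.
Standard errors use the HC3 sandwich covariance (velocity noise is
roughly multiplicative, so Hanes residuals are heteroscedastic; the
homoscedastic OLS covariance under-covers by ~30%) propagated by the
delta method.  Default grids are {0.2, 0.5, 1, 2, 5} × a pilot Km from
a coarse deterministic scan, giving leverage on both sides of Km.

**Exponential fits.** y(t) = A(1−e^(−Bt)) by bounded nonlinear least
squares; the start point is deterministic (A₀ = 1.05·max y, B₀ from the
slope of −log(1−y/A₀)), with a few perturbed restarts.  B is k_tran
when the enzyme–adenylate complex is pre-formed, k_chem when everything
is mixed at t = 0.

**Burst detection.** A line is fitted to the late half of the product
trace; the burst amplitude is its t = 0 intercept and the flag fires at
≥ 0.5 product per catalytic site.  Steady-phase stationarity is checked
by splitting the tail into three windows whose slopes must agree within
10% or within three counting-noise standard errors (cumulative counts
have random-walk residuals, so OLS slope errors are meaningless and the
Poisson error of the window increment is used instead).  Stochastic
burst assays average the product curve over 10 replicates before
extrapolating, and the qualitative burst call is best made on the
mean-field curve: a real cuvette holds ~10¹¹ enzymes, so the observed
curve is the ensemble mean, while at a few hundred simulated copies the
0.5/site threshold lies within counting noise of cysRS's true amplitude
(~0.52/site under the standard burst conditions — the class I burst is
intrinsically marginal at 10 µM tRNA given kcat ≈ 3 s⁻¹,
k_tran ≈ 15 s⁻¹ and Km_tRNA ≈ 1 µM).

## Staged parameter identification

The three assays probe nested subsections of the mechanism, so fitting
proceeds in stages that progressively freeze parameters; all stage
observables are computed with the deterministic stationary/ODE pipeline,
making a fit a pure function of its inputs and seed.

1. **Single turnover.**  Only the transfer rate is identifiable here
   (binding is pseudo-first-order and fast at 50 µM enzyme; AMP and
   product release are downstream of the counted transfer event), so the
   stage tunes and freezes the transfer pair to match k_tran.
2. **Pyrophosphate exchange.**  Twelve parameters, of which four
   dimensions dominate kcat/Km: the amino-acid and ATP dissociation
   constants, the activation pair and the PPi release rate.  Damped
   multiplicative updates (kcat ← activation scale, each Km ← the
   corresponding off-rates) converge in a few iterations; insensitive
   parameters keep constrained or default values.
3. **Aminoacylation.**  The remaining dimensions are the tRNA on/off
   rates (the adenylate state S5 is the high-affinity entry point;
   substrate-free states get 0.3× its on-rate, because early tRNA
   binding routes flux through the slow amino-acid-capture branch and
   degrades k_chem), the amino-acid and ATP dissociation constants with
   tRNA bound, and the product-release rates — the kcat knob for
   monomers; for flip-flop dimers the site-1 release pair gated by
   site-2 activation plays that role.  Adenylate-formation rates with
   and without tRNA are tied.  A seeded log-normal refinement follows
   the multiplicative loop when needed, with the turnover number
   weighted most heavily and, for burst-positive enzymes, a hinge that
   pushes the burst amplitude clear of the 0.5/site decision boundary
   (margin is bought with few-percent shifts inside the 15% target
   tolerances, never by moving the threshold).

Constraints pin K_d, k_on or k_off of any step bitwise.  Defaults for
unconstrained dimensions: amino-acid k_on 5 µM⁻¹s⁻¹ (rapid equilibrium),
ATP k_on 0.1–0.2 µM⁻¹s⁻¹, tRNA capture nearly committed (small k_off),
release steps fast unless they are the fitted kcat bottleneck.  The
with-tRNA amino-acid off-rate is capped at 60× the activation rate:
beyond that the tRNA-bound branch becomes a kinetic dead end while the
apparent Km_aa saturates anyway (the tRNA-free capture path takes over).

Two deliberate softenings, both consequences of the scheme's structure:
k_chem is scored but gated only through the qualitative band
k_chem/k_tran ∈ [0.8, 1.3], because the amino-acid capture time implied
by a fixed aminoacylation Km_aa bounds k_chem below ~0.85·k_tran for
cysRS-like parameters; and the simulated single-turnover rate of a
finished model can sit up to ~15% above its stage-1 target for
high-tRNA-affinity enzymes, because later stages legitimately shorten
the tRNA-binding delay that was present when the transfer rate was
calibrated.

**Packaged models.**  cysRS (class I monomer) and hisRS (class II
flip-flop) are fitted to consensus in-vitro observables (for hisRS's
aminoacylation Km_aa the consensus of the published measurements,
7.0 µM, is used) with five restarts; the restart with the smallest
weighted log-distance to the targets is frozen in
`src/aakin/data/rates.tsv`, and the achieved observables are recorded
alongside in `enzymes.json`.  Parameter *values* are not claimed
identifiable — only observables are; the recovery property is checked on
random ground-truth enzymes.

## Michaelis–Menten reduction

The reduced model is v = kcat[E0][S]/(Km+[S]) with ATP assumed
saturating throughout; the multi-isoacceptor form shares the enzyme
through the competition denominator 1 + Σⱼ[Tⱼ]/Kmt(j).  The rescaling
relation is implemented as kcat′ = r(Km′+[Tu])/[Tu] — the unique kcat
giving velocity r at substrate [Tu] under the new Km — and satisfies
the defining identity to machine precision.  `derive_mm_from_full_model`
extracts MM parameters from any full model by running the aminoacylation
Km assays (deterministic by default, stochastic on request); whether a
reduced parameter set originates from that route or from direct assay
fits, both paths are provided.

## Cell-scale meta-analysis

Consensus densities are Gaussian mixtures p(y) = (1/A)Σᵢexp(−(y−yᵢ)²/2σᵢ²)
with A = Σᵢ√(2π)σᵢ (unit integral); measurements without a reported
error get a default 20% relative σ.  The evaluation grid spans
[min(y)−4σmax, max(y)+4σmax] at 2000 points and the consensus value is
the grid argmax.  Turnover rates are r = a/n with a the per-cell
amino-acid usage (µM/s × 602.214 × volume in µm³ → molecules/s) and n
the enzyme copy number.

Transcriptome reconstruction normalises RPKM values to fractions x(i),
scales by α so the nucleotide total matches the target for the growth
rate of interest, and rounds copy numbers by largest remainder (the
realised total stays within one mRNA length of the target).  Codon
usage weights each CDS's codon counts by its copy number.

The demand simulation couples each enzyme's full charging scheme to a
Poisson consumption drain (free charged tRNA → free uncharged tRNA at
the demanded rate) and reports the time-averaged partition over the
final half of the run: charged fraction, enzyme-bound fraction, and the
realised velocity against the demand.  Demand beyond the enzyme's
capacity is reported as unsustainable (charged-pool collapse), not an
error.  This drain deliberately replaces ternary-complex formation,
Ef-Tu cycling and ribosome kinetics with a single channel per
isoacceptor: ribosome- and ternary-complex-bound tRNA partitions, bulk
charging fractions across all 20 enzymes, and elongation-speed
predictions are out of scope.

## Synthetic data

`make_mm_oracle_fixture` builds a two-state mechanism whose stationary
velocity is exactly kcat[T]/(Km+[T]) (Briggs–Haldane by construction),
used to calibrate the assay → estimator pipeline end to end.
`make_synthetic_enzyme` draws log-uniform rate multipliers within a
factor of three of the package defaults and packages the model's own
simulated observables as fit targets, giving ground-truth recovery
problems.  These fixtures emulate the *kinetic structure* of the real
assays — they do not emulate pipetting error, quench-time jitter,
radiolabel counting statistics or temperature effects, so passing tests
demonstrate correctness of the simulation/estimation machinery, not
robustness to real experimental noise.

## Problem sizes and numerical choices

Velocity assays use 50–200 enzyme copies with 10 replicates per
concentration and 5-point grids; single-turnover runs track 500 tRNA
molecules against 5000 enzymes; burst assays use 500 copies × 10
replicates (SSA) at ≤10 ms sampling; the demand simulation defaults to
a 1 µm³ cell.  Stationary distributions come from a dense linear solve
(schemes have ≤ 20 states); ODE integration uses LSODA with rtol 1e-8.
Exponential fits error out rather than return amplitudes more than 10%
above the available tRNA.  Ties in largest-remainder rounding follow
numpy's stable argsort.  All stochastic entry points take explicit
seeds; identical seeds give bitwise-identical trajectories.

## Known limitations

* The flip-flop state list models site 2 without bound tRNA; recruitment
  of the next tRNA happens after the flip.  This preserves the
  half-of-sites phenomenology but is a coarser graph than a full
  two-site enumeration.
* Rate-constant values are effective, not microscopic: many directions
  are unidentifiable from steady-state observables and sit at
  convention-based defaults.
* Thermodynamic consistency (detailed balance around binding cycles) is
  not enforced beyond structural reversibility.
* The in-vivo demand simulation is a single-enzyme caricature of
  translation; it cannot reproduce whole-cell charging fractions or
  ribosome speeds.
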