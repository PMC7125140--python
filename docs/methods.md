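# Methods

## The model class

`oscidesign` works with kinetic models in Generalized Mass Action (GMA)
form: each dynamic variable obeys

    dx_i/dt = Σ_j a_j Π_k x_k^{g_jk}  −  Σ_j b_j Π_k x_k^{h_jk},

with strictly positive coefficients (products of named parameters) and real
exponents. Saturating (Michaelis/Hill-type) regulation is accommodated
without leaving this algebra by a *denominator auxiliary*: an inhibition
v·K/(K + z) is written as the term `v*K*D^-1` with the algebraic relation
`D = K + z`. Pure power-law auxiliaries (e.g. a binding-equilibrium complex
`c = K_A*x*s`) are substituted away exactly before analysis; multi-term
auxiliaries are retained because each of their summands can dominate.

## Dominance phenotypes and S-systems

For fixed parameters and state, one production and one consumption term of
every equation is numerically largest. A *phenotype* is one such choice for
all equations (including one summand per retained denominator). Keeping
only the dominant pair gives an S-system, which is log-linear at steady
state: with q = log10 p and u = log10 x,

    A_d u = R q + r   ⇒   u = W q + w0   (closed form, unique),

provided A_d is invertible. Phenotypes with singular A_d are recorded as
*degenerate* and excluded from sampling; for the built-in cell-cycle
designs these are mostly choices in which two equations impose proportional
log-linear constraints. Each neglected term yields one linear *boundary*
inequality log10(dominant) ≥ log10(neglected); eliminating u through the
steady-state relation leaves inequalities in q alone, so validity of a
phenotype inside the global parameter box is a linear program.

Phenotypes are enumerated in a documented mixed-radix order (equations in
model order, the production index the major digit within an equation,
1-based `case_id`). This numbering is internal to the package; it does not
correspond to the case numbers of any other design-space implementation.

The validity LP maximises the minimum normalised boundary slack
(a Chebyshev-centre-style program). This yields in one solve a strictly
interior witness point where the dominant terms strictly dominate — the
role a boundary vertex shifted toward the analytic centre would play, with
no tie handling needed.

## Eigenvalue screening

Stability is assessed on the dominant subsystem: the analytic power-law
Jacobian of the two-term S-system at its closed-form steady state. A
sample has *oscillatory potential* when a complex-conjugate eigenvalue pair
has non-negative real part (the necessary condition for a limit cycle born
at a Hopf bifurcation; zero real part counts, with a relative tolerance of
1e-9 on the spectral radius). This is a screening filter, not a proof:
the full model's Jacobian can differ from the subsystem's, so oscillations
can be missed (false negatives are accepted for tractability) and screened
samples can turn out stable (they are integrated and classified anyway).

## Sampling a phenotype

Starting from the LP witness, the parameters are shuffled into a fresh
random order for every point; each parameter in turn receives its 1D
*phenotypic tolerance* — the interval within which all boundaries remain
satisfied given the values already fixed, intersected with the global
bounds [1e-9, 1e3] — and is drawn uniformly in log10 within it. Every
finished point therefore satisfies all boundaries by construction; the
shuffle removes the order bias that a fixed sweep would imprint on the
joint distribution. Randomness comes from a per-sample substream seeded by
(run seed, design name, case_id, sample index), which makes runs bit-
reproducible and the record set at a smaller sample count a subset of a
larger one under the same seed.

If the tolerance chain collapses numerically (an empty interval), the point
is retried with a fresh shuffle up to 10 times and then skipped with a log
entry.

## Limit-cycle detection

Full-model trajectories start from the phenotype's steady state with one
species (the first observable) multiplied by 1.01 — starting exactly on an
unstable fixed point can stall for many windows before round-off seeds the
escape. Integration proceeds in 500-minute windows with dense output every
0.1 min up to a 10,000-minute horizon, using lsoda, then implicit BDF,
then dopri5 whenever a method fails.

The classifier applies, per window:

* **limit cycle** — every observable shows ≥ 5 *qualifying maxima* (local
  maxima within 5% of the window maximum) in a repeating pattern matching
  the expected circular order Sic1 → Clb5 → Clb3 → Clb2; every species'
  amplitude is ≥ 10% of its window maximum; the window maxima across
  species stay within 100-fold; and each species keeps peaking in the
  second half of the window (a damped transient fails this). The period is
  the mean spacing of the last-peaking species' (Clb2) qualifying maxima.
* **steady state** — no species moves by more than 1% of its global
  maximum over the window.
* otherwise integration continues; at the horizon the verdict is
  **undetermined**; integrator breakdown or |x| > 1e12 is
  **integration_failure**.

Consequences worth knowing: oscillations with amplitude below 10% (small
cycles near a supercritical Hopf point) and sub-1% micro-oscillations are
deliberately not counted as limit cycles; periods above ~100 min cannot
produce 5 peaks in a 500-min window and end as undetermined; periods below
a few tenths of a minute are unresolvable on the 0.1-min grid.

### Numerical representation

Trajectories are integrated in log-concentration space (u = ln x). After
log-uniform sampling, steady-state magnitudes routinely span 1e-11 to 1e6
across species; a fixed absolute tolerance in linear space destroys the
small species and permits negative excursions, whereas in log space
positivity is structural and the tolerance is uniformly *relative*. In u
the power-law terms are exponentials of affine functions, evaluated by a
small JIT kernel when numba is available (a pure-numpy fallback gives
bit-equivalent results).

Each integration carries a deterministic work budget counted in RHS
evaluations (healthy windows need ~1–2 evaluations per output point): a
method exhausting its per-window budget counts as failed and the chain
falls through; a trajectory exhausting its total budget is an
integration failure. Budgets are counts, not wall time, so results are
machine-independent.

## The cell-cycle designs

The 11 designs describe three Clb/Cdk1 complexes (x = Clb5/Cdk1 for S
phase, y = Clb3/Cdk1 for G2, z = Clb2/Cdk1 for M) and their stoichiometric
inhibitor Sic1 (s, G1), with basal synthesis/degradation (v, β),
transcriptional activations — the linear cascade Clb5 → Clb3 (α_xy) and
Clb3 → Clb2 (α_yz), the feed-forward Clb5 → Clb2 (α_xz), and the Clb3/Clb2
positive feedback loops (α_yy, α_zz) — and APC-mediated inhibitions
(γ terms). Ternary-complex formation between each Clb/Cdk1 and Sic1
degrades Sic1 (δ channel) and the Clb subunit (ε channel).

Designs 1A–1C and 2 carry the three complexes as dynamic species with
mass-action binding (k_plus, k_minus); designs 3–9 assume the binding
equilibrates fast (QSSA) with association constant K_A, so `c_i = K_A·i·s`
enters as a pure power-law auxiliary. Designs 4–9 each add one saturating
transcriptional inhibition to design 3 with a design-specific constant
(K_zx, K_zs, K_cs, K_sm, K_sc, K_ss).

The packaged model files are a *documented reconstruction* of this
interaction set and are the package's single source of truth. Two points
of the reconstruction deserve emphasis:

* **Mass-action ⇌ QSSA consistency.** In designs 1A–2 the degradation
  channels release the surviving binding partner (δ·c_i returns the Clb,
  ε·c_i returns Sic1, k_minus·c_i returns both), which makes the fast-
  equilibrium limit of design 2 reduce exactly to design 3's flux
  structure. The free-species QSSA additionally neglects the material
  buffered in the complex pool, so the reduction is quantitative only when
  K_A·s ≪ 1; the convergence test uses a weak-binding parameter set and a
  k_minus ladder in the regime where the equilibration error dominates.
* **Progression 1A → 2.** The deltas between the mass-action designs are
  reconstructed as a monotone build-up towards design 3: 1A is the core
  without the two hypothetical PFLs and without the Clb self-inhibitions,
  plus a lumped Cln/Cdk1-mediated degradation of free Sic1 (k_cln); 1B
  adds the PFLs; 1C adds the self-inhibitions; 2 removes the Cln channel
  and is the exact mass-action counterpart of 3.

Design 6's "all Clb/Cdk1 complexes inhibit SIC1 transcription" is encoded
with a single summed denominator `D = K_cs + x + y + z` (four dominance
regimes); the alternatives (three separate factors) would multiply the
phenotype count by 8 instead of 4 with no change in the dominant-term
algebra.

Parameter counts: design 3 has 21 rate constants; designs 4–9 have 22 (the
added K); designs 1A–2 replace K_A by k_plus/k_minus. When limit-cycle
parameter sets are pooled across designs for PCA, the per-design K
constants are merged into one column, giving the common 22-dimensional
space.

## Fixture oscillators

* `negative_feedback_3node` — a three-step Goodwin-type loop in power-law
  form, `x1' = a*x3^-10 - b*x1; x2' = c*x1 - d*x2; x3' = g*x2 - f*x3`.
  At equal unit rates the fixed point is (1,1,1) with eigenvalues
  λ = −1 + p^{1/3} e^{±iπ/3} for repression exponent p, so the Hopf
  threshold is p = 8 and the packaged p = 10 oscillates (period ≈ 4 time
  units). It exercises the entire pipeline end to end at desk scale.
* `lotka_volterra` — the conservative predator–prey system; its fixed
  point has eigenvalues ±i√(ad), the canonical boundary case for the
  "non-negative real part" convention.
* `linear_chain` — a feed-forward relaxation chain, real negative
  eigenvalues everywhere: the guaranteed-negative control.

What the fixtures do *not* emulate: the cell-cycle designs' multi-scale
parameter spreads, denominator auxiliaries, multi-stability, and the
four-species circular order constraint. Tests passing on fixtures
establish the machinery's correctness, not the biology of the yeast
designs.

## Screen conditions and problem sizes

A full-scale screen (the study condition) samples every valid phenotype
250 times within bounds [1e-9, 1e3]. For design 3 the package's
reconstruction has 2304 phenotypes (2·10³–10⁴ scale; the count is a
property of the reconstruction's term structure, not a universal
constant), of which roughly 60% are LP-valid and 40% degenerate.
Limit cycles passing all acceptance rules are rare — of order one per
10⁴–10⁵ eigenvalue-screened samples — consistent with the sparseness that
motivates design-space screening in the first place.

The test suite and the acceptance script run a scaled-down screen
(25 samples per phenotype, several seeds) so that a complete
enumeration–LP–sampling–integration pass finishes in minutes on one CPU;
the summary counts they print are therefore themselves stochastic
quantities with seed-to-seed variation, and the per-phenotype "potential"
counts scale roughly linearly with the sample budget.

## Analyses

Correlations and PCA operate on log10 parameter values (standardised to
zero mean, unit variance for PCA), because raw values spanning twelve
decades would let single parameters dominate. Period sensitivities are
central log-differences ∂lnT/∂lnp with a 1% relative step, re-integrating
the full model per perturbation; parameters whose perturbation loses the
cycle are reported as such. The dimensional-analysis check Σ_p ∂lnT/∂lnp
= −1 over all rate coefficients (scaling all coefficients by λ rescales
time by 1/λ) holds on the fixture oscillator to within the finite-
difference and period-measurement error. 1D bifurcation scans report the
full-model oscillation envelope alongside every valid phenotype's
steady-state branch and positive-eigenvalue count (line-style data for
multi-stability); 2D robustness scans record raw sampled amplitudes and a
thin-plate-spline RBF interpolation that is presentation-only.

## Known limitations

* The eigenvalue screen inherits the dominant-subsystem approximation;
  designs whose full-model oscillations live in phenotypes with stable
  subsystem spectra are systematically missed.
* Detection windows bound the measurable period range (~0.5–100 min at
  the default settings).
* Degenerate phenotypes are excluded rather than analysed hierarchically;
  co-dominance (ties) is handled by non-strict inequalities and an
  interior witness, not by dedicated boundary cases.
* The packaged equations are a reconstruction; every structural choice is
  stated here and in the model-file comments, and all downstream numbers
  are conditional on it.
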