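# oscidesign

Design-space screening for autonomous limit-cycle oscillations in
power-law kinetic models — with the minimal budding-yeast Clb/Cdk1
cell-cycle network built in.

## The problem

Finding parameter sets for which a nonlinear biochemical model oscillates
is hard: limit cycles occupy thin, scattered regions of parameter spaces
that span many orders of magnitude, and brute-force sampling almost never
lands on them. For models in Generalized Mass Action (GMA) form —
every rate a signed sum of power-law terms,
dx_i/dt = Σ a_j Π x^g − Σ b_j Π x^h — the *system design space*
decomposition makes the search tractable. For any fixed parameters and
state, one production and one consumption term per equation dominates
numerically; each such choice (a **phenotype**) reduces the model to an
S-system that is log-linear at steady state:

    A_d·u = R·q + r,   u = log10(x*),  q = log10(p),

solvable in closed form, with one linear boundary inequality per neglected
term (log dominant ≥ log neglected). Whether a phenotype is realisable
inside the global parameter box is then a linear program. The screening
pipeline is:

1. enumerate all phenotypes; keep the LP-feasible (**valid**) ones;
2. sample each valid phenotype log-uniformly inside its boundaries
   (shuffled per-parameter tolerance chain, so every sample is valid by
   construction);
3. screen each sample's closed-form steady state for a complex-conjugate
   eigenvalue pair with non-negative real part (the Hopf necessary
   condition — **oscillatory potential**);
4. integrate the *full* model from that steady state and accept a
   **limit cycle** only if every species shows ≥ 5 near-maximal peaks in a
   repeating pattern with the right temporal order, ≥ 10% amplitude, and
   < 100-fold spread across species maxima.

The package ships 11 designs of a minimal cell-cycle oscillator for
budding yeast — the S/G2/M cyclin/Cdk1 complexes Clb5/Cdk1, Clb3/Cdk1,
Clb2/Cdk1 and their stoichiometric inhibitor Sic1, with the linear CLB
cascade (Clb5 → Clb3 → Clb2), positive feedback loops, APC-mediated
inhibitions and Clb/Cdk1/Sic1 ternary-complex degradation — as plain-text
model files (see `docs/methods.md` for the equations' provenance and all
numerical conventions).

## Worked example

Screen the built-in three-node negative-feedback fixture (a Goodwin-type
power-law loop with a known Hopf threshold) and inspect the result:

```python
import oscidesign as od

model = od.make_fixture_oscillator("negative_feedback_3node")
result = od.run_design_screen(model, samples_per_phenotype=100,
                              seed=1, bounds=(0.1, 10.0))
print(od.summarize_counts(result))
for rec in result.records[:3]:
    print(rec.case_id, round(rec.period, 2), rec.peak_order)
```

```
{'design': 'negative_feedback_3node', 'total_phenotypes': 1,
 'valid_phenotypes': 1, 'degenerate_phenotypes': 0,
 'oscillatory_potential': 1, 'phenotypes_with_limit_cycles': 1,
 'limit_cycles_retrieved': 7}
1 2.11 ('X1', 'X2', 'X3')
1 9.18 ('X1', 'X2', 'X3')
1 1.14 ('X1', 'X2', 'X3')
```

One phenotype exists (each equation has a single term per side), it is
valid everywhere, and 7 of 100 log-uniform samples inside `[0.1, 10]`
produced verified limit cycles; each record carries the period (in the
model's time unit) and the circular peak order — here the cascade
X1 → X2 → X3.

The cell-cycle designs work identically but at scale — Design 3 has 2304
phenotypes, of which about 1400 are valid — and limit cycles are rare
(the point of the targeted search). The same run from the shell:

```bash
oscidesign screen --design 3 --samples 250 --seed 42 --out results/
oscidesign designs --list
```

writes `result.json`, `table1.csv` (phenotype counts), `table2.csv`
(parameter occurrence in dominant terms of limit-cycle phenotypes),
`samples.csv` and `limit_cycles.csv`. Post-screen analyses — Pearson
correlations and PCA of limit-cycle parameter sets, period sensitivities
∂lnT/∂lnp, 1D bifurcation envelopes, 2D robustness heatmaps and phenotype
phase planes — live in `oscidesign.analysis` and behind the `analyze`,
`bifurcate`, `robustness` and `phaseplane` subcommands.

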