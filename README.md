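# paleobrain

Phylogenetic comparative analysis of brain size and brain-region
proportions versus locomotor behaviour on fossil-bearing trees.

Paleoneurology asks how the brain and its regions — neocortex, olfactory
bulbs, petrosal lobules — scaled and reorganised as lineages changed
lifestyle over millions of years.  The data are virtual endocasts of
extant and extinct species (volumes and surface areas), a locomotor
classification (arboreal, fossorial, glider, scansorial, terrestrial), and
a rooted topology whose fossil tips are dated only to stratigraphic
intervals.  Because species share evolutionary history, ordinary
regression understates uncertainty and misattributes signal; every
inference here can account for the phylogeny.

The package provides, as a tested library plus a thin CLI:

* **Time-calibration** of a fixed topology from fossil age bins: tip ages
  drawn uniformly within their intervals, stochastic node dating above a
  minimum branch length, 100-tree sets and a mean-age average tree.
* **PGLS** — `β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y` with the error covariance V built
  under Brownian motion, Pagel's λ, Early Burst, or Ornstein–Uhlenbeck;
  ML profile estimation of the covariance parameter; two-stage AIC
  selection over formulas and models; sequential (Type I) F tests.
* **PEQ** — the phylogenetic encephalization quotient
  `PEQ = E_i / (a·M^b)` with `a, b` taken from the PGLS allometry of
  log10 endocranial volume on log10 body mass (Jerison's classic
  `EQ = E_i / (0.12·M^0.67)` is also computed).
* **Group tests** — asymptotic K-sample Fisher–Pitman permutation tests
  and pairwise comparisons with Benjamini–Hochberg adjustment, plus
  Shapiro–Wilk/Bartlett/Levene preconditions.
* **RRPP ANOVA** — non-phylogenetic ANOVA by residual randomization with
  least-squares-mean post-hoc pairwise tests.
* **Ancestral states** — ML (GLS) reconstruction of continuous traits
  under Brownian motion, and stochastic character mapping of the
  locomotor character under an equal-rates Markov model with the
  empirical rate.
* **Synthetic data** — a generator producing study-shaped datasets
  (38 tips, 13 of them fossil; allometry with phylogenetically correlated
  residuals; five-state locomotion) with a full ground-truth record, so
  every stage is testable end to end.

See `docs/methods.md` for models, defaults, and design decisions.

## Worked example

```python
from paleobrain.synthetic import SynthConfig, simulate_dataset
from paleobrain.pipeline import analyze

ds = simulate_dataset(SynthConfig(seed=1))
bundle = analyze(ds.traits, ds.tree, ds.age_bins, seed=1,
                 n_calibration_trees=100, rrpp_iterations=1000, n_simmaps=1000)

m = bundle.allometric_model
print(f"PEQ allometry: E_c = {m.a:.3f} * M^{m.b:.3f}")
row = bundle.table1[(bundle.table1.response == "peq")
                    & (bundle.table1.comparison == "k-sample")].iloc[0]
print(f"PEQ locomotor test: chi2 = {row.statistic:.3f}, df = {row.df}, p = {row.p_value:.4f}")
roots = bundle.asr_nodes[bundle.asr_nodes.is_root].set_index("trait").estimate
print(f"Reconstructed root: Neo% = {roots['neo_pct']:.1f}, "
      f"PL% = {roots['pl_pct']:.2f}, OB% = {roots['ob_pct']:.1f}")
print(f"Mk-ER rate: q = {bundle.mk_fit.q:.4f} / Myr")
```

prints

```
PEQ allometry: E_c = 0.543 * M^0.564
PEQ locomotor test: chi2 = 22.759, df = 4, p = 0.0001
Reconstructed root: Neo% = 17.6, PL% = 1.22, OB% = 6.1
Mk-ER rate: q = 0.0198 / Myr
```

Reading this: the fitted allometric exponent 0.564 estimates the
generating slope 0.57 (the coefficient 0.543 vs 0.42 reflects intercept
extrapolation to 1 g, which is noisy at n = 38); PEQ differs strongly
across locomotor groups (χ² on 4 df); the reconstructed root proportions
sit near the generating baselines (18.3%, 1.25%, 5.8%); and the locomotor
character changes at ~0.02 transitions per state pair per Myr.  The same
run also fills `bundle.table2` (six selected PGLS regressions),
`bundle.table3` (RRPP pairwise p-values), and per-node reconstruction
tables; `bundle.write(outdir)` exports everything as CSV/Newick.

The CLI mirrors the library: `paleobrain simulate`, `calibrate`,
`analyze`, `compare-topologies`, `reproduce-tables`; `analyze` takes a
single YAML config with the input paths, the master seed, and iteration
counts, and writes the full output bundle plus a run log.

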