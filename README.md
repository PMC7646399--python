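# impcox

Multi-stage variable selection for high-dimensional survival data with
gene–gene interactions, plus the companion statistics used in studies that
link tumor expression profiles, survival time, and protein-level
validation: RPPA differential-protein calling, IQR variance prefiltering,
2×2 chi-square association testing, and time-dependent ROC/AUC evaluation
of risk scores.

The motivating setting is glioblastoma multiforme (GBM): a few hundred
tumors with survival follow-up and ~10⁴ gene expression values each
(P ≫ N), where the goal is a small, interpretable gene signature — and
where purely additive models miss the gene–gene interactions that drive
biology.

## The algorithm

For sample *i* with covariates *xᵢ*, the Cox proportional-hazards model
puts hazard *h(t | xᵢ) = h₀(t) exp(xᵢᵀβ)*, fitted by maximizing the
Breslow log partial likelihood

```
ℓ(β) = Σ_{k∈D} [ x_kᵀβ − d_k · log Σ_{j∈R_k} exp(x_jᵀβ) ]
```

where *D* indexes distinct event times, *d_k* counts tied events, and
*R_k* is the risk set at time *t_k*. **ImpCoxSisLasso** chains four
stages:

1. **Lasso screen** — minimize *−ℓ(β) + λ Σ|βⱼ|* over all genes;
   the nonzero support is C₀.
2. **Conditional screen** — for every gene *m ∉ C₀*, jointly refit the
   Cox model on C₀ ∪ {m}; keep *m* in C₁ when the Wald p-value of its
   coefficient is below 1/p (a conditional sure-independence screen).
3. **Lasso refit** — a fresh penalized fit restricted to Θ = C₀ ∪ C₁;
   the support is the final main-effect set C.
4. **Interaction fit** — unpenalized Cox MLE over all main effects in C
   plus every pairwise product *x_{i₁}·x_{i₂}* (i₁ ≠ i₂ ∈ C), with an
   L1 fallback when the parameter count reaches the event count.

Comparators **CoxLasso** (stage 1 only), **CoxSis** (marginal screen +
Cox fit), and **CoxSisLasso** (stages 1–3) are provided, along with
gene-level Venn intersection of their selections.

The companion RPPA module calls differential proteins from replicated
reverse-phase protein array experiments: fold change
*FCᵢ = Σⱼ ExPᵢⱼ / Σⱼ CoPᵢⱼ* (ratio of replicate sums), judgement UP if
FCᵢ > 1 and DOWN otherwise, and a per-protein two-sample t-test at a raw
p < 0.05 cutoff.

## Worked example

```python
import impcox as ic

spec = ic.SurvivalSimSpec(n=200, p=1000, seed=7)   # 5 mains, 2 interactions
dataset, truth = ic.simulate_survival(spec)
result = ic.run_impcoxsislasso(dataset, ic.SelectionConfig(seed=7))

print("true main-effect genes:   ", sorted(truth.main_names))
print("selected main effects (C):", result.main_effect_names)
prec, rec, f1 = ic.score_support(result.main_effect_names, truth.main_names)
print(f"support recovery: precision={prec:.2f} recall={rec:.2f} F1={f1:.2f}")
```

prints (exact output of this snippet):

```
true main-effect genes:    ['G0000', 'G0010', 'G0020', 'G0030', 'G0040']
selected main effects (C): ['G0000', 'G0010', 'G0020', 'G0030', 'G0040']
support recovery: precision=1.00 recall=1.00 F1=1.00
```

i.e. on this draw the pipeline recovers exactly the five true
main-effect genes out of 1000; the final model also carries the
pairwise interaction terms among them (`G0000_G0010`, ...). Training on
a stratified 70% split and scoring the held-out 30% with the
IPCW time-dependent ROC at the median follow-up gives

```
held-out AUC at t*=9.8: 0.645 (25 cases, 32 controls)
```

From the shell, the same pipeline is available as subcommands:

```bash
impcox simulate --preset desk --seed 7 --out-prefix sim
impcox select --matrix sim.matrix.tsv --survival sim.survival.tsv \
              --algorithm impcoxsislasso --seed 7 --out selection.json
impcox chi2 18 11 2 7
```

The last command tests independence of two binary immunohistochemistry
stainings (EGFR status vs AEBP1 status across 38 tumors) and prints

```
{"statistic": 4.374286930608769, "p_value": 0.03648509296485496}
```

— an uncorrected Pearson chi-square with 1 df; p < 0.05 indicates the
two markers co-occur more than chance predicts.

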