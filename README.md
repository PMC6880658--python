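# lldnet

Symptom-network analysis of late-life depression (LLD) with comorbid
anxiety.

Clinically, anxiety is the most common comorbidity of depression in older
adults, and it worsens outcomes — but *how* it acts is ambiguous: it may
increase symptom severity, or it may rewire the relationships among
depressive symptoms (the psychopathological network). `lldnet` implements
the full statistical workflow needed to separate those two hypotheses in
cohorts rated on the Montgomery–Åsberg Depression Rating Scale (MADRS,
10 items scored 0–6) and the Beck Anxiety Inventory (BAI, 21 items scored
0–3):

1. **Cohort handling** — CSV readers/writers with strict validation,
   severity eligibility (MADRS sum ≥ 10), diagnosis exclusions, and the
   BAI ≥ 16 anxiety split.
2. **Association** — polychoric correlations between ordinal items and a
   polyserial anxiety node from the BAI sum, with PSD repair.
3. **Network estimation** — a Gaussian graphical model fitted by graphical
   lasso over a penalty path with EBIC (γ = 0) selection; edge weights are
   partial correlations −K_ij/√(K_ii K_jj).
4. **Centrality** — strength Σ|w|, and closeness/betweenness on 1/|w|
   shortest paths.
5. **Resampling** — bootstrap edge-weight CIs and the case-dropping
   CS coefficient for centrality stability.
6. **Comparison** — the permutation Network Comparison Test (global
   strength, global structure = max edge difference, Holm-adjusted
   per-edge tests), refitting the full estimation chain per permutation.
7. **Matching** — 1:1 nearest-neighbor propensity-score matching (logistic
   model on MADRS sum, age, sex, education; caliper 0.25 SD of the logit
   propensity) to remove the severity confound before re-comparing
   networks.
8. **Synthetic cohorts** — a latent-Gaussian threshold generator with a
   known sparse network, three symptom clusters, and an anxiety factor
   whose *severity shift* confounds group comparisons by design, so every
   stage can be validated against gold-standard truth.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import pandas as pd
from lldnet import (
    CohortTable, GlassoConfig, apply_eligibility, association_matrix,
    centrality_table, fit_network, generate_cohort, match_cohort,
    nct, preset_lld, split_by_anxiety,
)
from lldnet.matching import matched_tables

# a 776-subject cohort whose high-anxiety stratum is ~7-9 MADRS points
# more severe, while both strata share one latent network
cohort, gold = generate_cohort(preset_lld("confounded_anxiety"), seed=7)
eligible = apply_eligibility(cohort)             # drops sub-threshold subjects
low, high = split_by_anxiety(eligible)
print(len(low), len(high))                       # 426 313
print(round(high.madrs_sum.mean() - low.madrs_sum.mean(), 1))   # 7.3

net = fit_network(association_matrix(eligible), eligible.n)
print(net.n_edges)                               # 29
top = centrality_table(net).to_dataframe().nlargest(3, "strength")
print(list(top.node))                            # ['m9', 'm2', 'm10']

pooled = CohortTable(pd.concat([low.df, high.df], ignore_index=True))
mres = match_cohort(pooled)
print(mres.n_matched)                            # 212
mlow, mhigh = matched_tables(pooled, mres)
res = nct(mlow, mhigh, GlassoConfig(n_lambda=20), n_perm=200, seed=7)
print(round(res.p_strength, 2), round(res.p_structure, 2))      # 0.98 0.91
```

The matched-sample comparison is null: once severity is balanced, the
high- and low-anxiety networks do not differ in global strength or
structure — severity, not psychopathology, carried the group difference.
The three strongest nodes (`m9` pessimistic thought, `m2` reported
sadness, `m10` suicidal thought) are the generator's seeded core symptoms;
the edge count (29) exceeds the 12 seeded edges because the shared
severity factor genuinely densifies the pooled-sample network.

A command-line interface mirrors the library
(`lldnet simulate|estimate|centrality|bootstrap|compare|match|table2|run`);
try `lldnet simulate --preset baseline_lld --out cohort.csv` followed by
`lldnet estimate --cohort cohort.csv --out net`.

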