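# noztree

Classification of raw, ungated multidimensional flow-cytometry (mFC) samples
with a tree-structured Bayesian network and a zero-probability cell statistic.

Conventional mFC analysis gates cells into subpopulations before comparing
groups, which is slow, operator-dependent, and discards information outside
the chosen gates. `noztree` instead uses *every* cell of *every* channel: it
learns the joint distribution of marker intensities from a pooled
healthy-control cohort as a Chow–Liu tree

    q(x) = P(x_root) · ∏_(c,p)∈tree Q(x_c | x_p),

where the spanning tree over markers maximizes total pairwise mutual
information and the factors are binned empirical count tables. A new sample is
scored by **NoZ** — the percentage of its cells whose probability under q is
*exactly* zero, i.e. cells whose binned marker pattern never occurred in the
control pool. Diseased samples containing aberrant cell subsets score high;
healthy samples score near zero. Groups are compared by Mann–Whitney U and
ROC/AUC, and the zero factors are attributed back to markers to rank which
channels drive the separation.

Intended users: immunologists and biostatisticians with per-cell CSV exports
(one header row of channel names, one row per cell) who want an automated,
gating-free two-group classification with full provenance.

## Worked example

```python
import numpy as np
from noztree import (BinningSpec, fit_tree_model, pool_controls,
                     score_sample, aggregate_marker_attribution)
from noztree.evaluation import evaluate_scores
from noztree.synthetic_data import default_config, simulate_cohorts

# a synthetic study: 20 control + 20 disease samples, 20 000 cells each,
# 10% of disease cells displaced 4 SD in markers M2 and M5
controls, diseases, truth = simulate_cohorts(default_config(seed=1))

pool, pooled_ids = pool_controls(controls, 10, seed=7)     # training cohort
model = fit_tree_model(pool, BinningSpec(50))              # HC tree, 50 bins

scores = [score_sample(model, t, "control")
          for t in controls if t.sample_id not in pooled_ids]
scores += [score_sample(model, t, "disease") for t in diseases]

result = evaluate_scores(scores)
print(f"AUC = {result.auc:.2f}, MWU p = {result.p_value:.2e}")
print("median NoZ:",
      f"disease {np.median([s.noz_percent for s in scores if s.label=='disease']):.2f}%",
      f"control {np.median([s.noz_percent for s in scores if s.label=='control']):.2f}%")
freq, _ = aggregate_marker_attribution([s for s in scores if s.label == "disease"])
print("top markers:", np.argsort(freq)[-2:])
```

prints

```
AUC = 1.00, MWU p = 1.20e-05
median NoZ: disease 8.78% control 3.56%
top markers: [5 2]
```

The held-out control samples keep a low NoZ (the few percent reflects
finite-sample support at 50 bins), every disease sample scores markedly
higher, the groups separate perfectly (AUC = 1), and the attribution recovers
exactly the two displaced markers.

The same pipeline is available from the shell:

```bash
noztree simulate --out-dir data --seed 1
noztree fit data/control_*.csv --n-bins 50 --n-pooled 10 --seed 7 --out model.json
noztree score data/disease_*.csv --model model.json --label disease --out scores.csv
noztree evaluate --scores scores.csv --out evaluation.json
noztree sweep --controls data --diseases data --k-markers 7 --out sweep.csv
```

Every command writes a `*.manifest.json` with the parameters, seeds and input
digests needed to reproduce it bit-identically.

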