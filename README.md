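# tbvnet

Weighted gene co-expression network analysis linking blood transcriptomes to
brain size.

`tbvnet` implements, as a tested Python pipeline, the network workflow used
to relate leukocyte gene expression in toddlers to total brain volume (TBV):
unsigned weighted co-expression networks, topological-overlap module
detection, module eigengenes, eigengene–trait association with permutation
and bootstrap inference, gene-level significance/connectivity (GS/GC)
reorganization statistics, small-vs-big-brain relevance classification,
module preservation between datasets, and hypergeometric gene-set
enrichment.  A synthetic-data generator plants known module structure and
trait coupling so that every stage is testable end to end without any
external download.

It is aimed at computational biologists who want a transparent,
dependency-light reimplementation of this class of analysis — for teaching,
for methodological work on network–trait association, or as a reference
against which to check other implementations.

## The model in brief

For genes *i, j* with expression profiles *x_i*, the unsigned network is

    a_ij = |cor(x_i, x_j)|^β,

with the soft power β chosen as the lowest value whose scale-free topology
fit index reaches 0.90.  Modules are detected by average-linkage clustering
of the topological overlap dissimilarity 1 − TOM, where

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

followed by an eigengene-membership (kME) rescue of unclustered genes.
Each module is summarized by its **module eigengene** (ME), the first
principal component of the module's standardized expression over samples.

Association statistics:

* **ME–trait correlation**: Pearson r of ME against age-adjusted TBV, with
  Student asymptotic p (t = r√(n−2)/√(1−r²), df = n−2), Storey q-values
  across modules, 95% percentile-bootstrap CIs (10,000 resamples by
  default), and a module-label-scrambling permutation p computed as
  count/(n_perm + 1).
* **Gene significance (GS)**: signed correlation of a gene with the trait;
  **gene connectivity (GC, kWithin)**: a gene's summed adjacency within its
  module.  Group differences in GS–GC correlation use the Fisher-z
  population statistic z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).
* **Hub/peripheral contrasts**: top-30 rankings per metric, 2×2 odds ratios
  with Haldane–Anscombe zero-cell correction, Woolf log-scale CIs, and the
  Fisher exact p on the uncorrected table.
* **Module preservation**: permutation Z statistics of density and
  connectivity in a test dataset; Zsummary < 2 no preservation, 2–10
  moderate, > 10 high.

## Worked example

Generate a two-group study with three planted modules — the first coupled
to the trait in controls (r = 0.6) but only weakly in cases — then detect
modules and associate eigengenes with the age-adjusted trait:

```python
from tbvnet import SyntheticConfig, generate_two_group_study, NetworkParams
from tbvnet.preprocessing import age_adjust_trait
from tbvnet.coexpression import (select_soft_power, build_adjacency,
                                 compute_tom, detect_modules,
                                 compute_module_eigengenes)
from tbvnet.module_trait import (module_trait_correlation, storey_qvalues,
                                 group_difference_permutation, PermutationSpec)

cfg = SyntheticConfig(
    n_genes=600, n_samples_per_group=(60, 60),
    module_specs=((70, 0.7), (60, 0.6), (50, 0.6)),
    trait_coupling={"M1": {"control": 0.6, "case": 0.2},
                    "M3": {"control": 0.0, "case": 0.5}},
    seed=0,
)
bundle = generate_two_group_study(cfg)
samples = age_adjust_trait(bundle.samples, method="spline", df=4)

params = NetworkParams()
power, fit = select_soft_power(bundle.expression, params)
tom = compute_tom(build_adjacency(bundle.expression, power))
partition = detect_modules(tom, params, expr=bundle.expression)
me = compute_module_eigengenes(bundle.expression, partition)

assoc = module_trait_correlation(me, samples, "control")
assoc["q"] = storey_qvalues(assoc["p"].to_numpy())
print(assoc.round(4).to_string(index=False))
```

Output (control group):

```
module   group  n       r      p      q
    M1 control 60  0.4741 0.0001 0.0004
    M2 control 60 -0.0555 0.6738 0.8624
    M3 control 60  0.0228 0.8624 0.8624
```

The planted M1 module is recovered exactly (70/70 genes; the run selects
β = 6) and its eigengene correlates with the trait in controls
(r = 0.47, q < 0.001 — attenuated from the planted 0.6 by eigengene
estimation) but not in cases (r = 0.04).  The case/control difference is
confirmed by the Fisher-z permutation test:

```python
gd = group_difference_permutation(me.me.loc["M1"], samples,
                                  PermutationSpec(n_perm=1000, seed=1))
# {'z_diff_obs': -0.472, 'perm_p': 0.014, 'n_case': 60, 'n_control': 60, ...}
```

zDiff = atanh(r_case) − atanh(r_control) = −0.47 with permutation
p = 0.014: the module–trait coupling is significantly stronger in controls,
exactly as planted.

The same pipeline runs from the shell:

```bash
tbvnet run-all --out-dir run1 --seed 0      # synthetic end-to-end run
tbvnet simulate --out study --seed 1        # write a study to disk
tbvnet network --expression study/expression.tsv --out-dir net
```

Every run writes TSV tables plus a `manifest.json` recording the seed,
per-stage seeds, parameters and outputs; reruns with the same seed are
byte-identical.

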