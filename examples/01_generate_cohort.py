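"""Generate a synthetic case/control multi-omics cohort with known truth.

Builds the default cohort the package's tests revolve around: 40 HCC
cases vs 49 cirrhosis controls measured on 100 proteins, 82 N-glycans
and 60 metabolites, with 24 planted differential features at a one-
standard-deviation log-scale shift and ~0.5% missing cells.
"""

import panelomics as po

table, labels, truth = po.generate_cohort(po.SyntheticSpec(seed=1))

print(f"cohort: {table.n_samples} samples x {table.n_features} features")
print(f"cases/controls: {labels.n_cases}/{labels.n_controls}")
for layer in ("proteomics", "glycomics", "metabolomics"):
    print(f"  {layer}: {len(table.layer_features(layer))} features")
print(f"missing fraction: {table.missing_fraction():.4f} (generator target 0.005)")
print(f"planted informative features: {len(truth.informative_features)}, "
      f"effect size d = {next(iter(truth.effect_size_of.values()))}")
print("first planted ids:", sorted(truth.informative_features)[:4])
# Every downstream stage consumes exactly this (table, labels) pair; the
# truth object is only used to score how well rankers recover the plant.
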