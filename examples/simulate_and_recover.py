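"""Generate a synthetic study and measure how well the pipeline recovers
the planted truth.

The generator plants baselines, per-gene biological CVs, correlated
blocks and condition-specific fold-changes; the recovery report compares
the pipeline's AVE, REV, fold-change and pair-class estimates against
those planted values.
"""

import pandas as pd

import genefabric as gf

spec = gf.SyntheticSpec(
    n_genes=120,
    conditions=("CO", "HO"),
    n_replicates=4,
    corr_blocks=(gf.CorrBlock(8, 0.99), gf.CorrBlock(8, 0.99, n_antagonistic=4)),
    regulation_effects=(("G0050", "HO", 5.0), ("G0051", "HO", -3.0)),
    seed=17,
)
table, truth = gf.generate_dataset(spec)
print(f"simulated {len(table.spot_ids)} spots for {spec.n_genes} genes, "
      f"{spec.n_replicates} replicates x {len(spec.conditions)} conditions")

profiles = {c: gf.gene_profiles(table, c) for c in table.conditions}
fab = {c: gf.fabric_summary(profiles[c]).set_index("gene") for c in table.conditions}
reg = gf.regulation_table(profiles["CO"], profiles["HO"], "CO", "HO")
pairs = gf.classify_pairs(profiles["CO"], "CO")

report = gf.recovery_report(
    truth,
    ave=pd.DataFrame({c: fab[c]["ave"] for c in table.conditions}),
    rev=pd.DataFrame({c: fab[c]["rev"] for c in table.conditions}),
    fold=reg.set_index("gene")[["x"]].rename(columns={"x": "HO"}),
    pairs=pairs,
    regulation=reg,
)

print(f"\nAVE relative bias : {report['ave_rel_bias']:+.3f} "
      "(0 = unbiased average expression)")
print(f"REV~CV Spearman   : {report['rev_cv_spearman']['CO']:.3f} "
      "(1 = REV perfectly ranks the planted biological CVs)")
print("\npair-class confusion (rows = planted, cols = called):")
print(report["pair_confusion"])
print("\nAt n=4 replicates the |COR|>=0.95 rule recovers only part of the")
print("planted coupling and fires on ~5% of truly independent pairs - the")
print("price of 4-replicate designs, not a defect of the estimator.")
print("\nregulation-call confusion:")
print(report["regulation_confusion"])
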