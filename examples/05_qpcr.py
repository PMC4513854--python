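"""qPCR quantification: percent input, fold over a control region, and
relative expression by 2^(-ddCt), with the unpaired t-test.

Numbers are illustrative Ct values of the kind a ChIP-qPCR validation
produces: a bound promoter amplicon, a gene-desert control, and an
expression knockdown measured against a reference gene.
"""

from cobind import (
    CtMeasurement,
    delta_delta_ct,
    fold_over_control,
    percent_input,
    ttest_unpaired,
)

# --- ChIP-qPCR: 1% of chromatin kept as input ---
promoter_ip = CtMeasurement("ht29", "TOP2A_promoter", (26.1, 26.3, 26.0))
promoter_in = CtMeasurement("ht29", "TOP2A_promoter", (24.6, 24.7, 24.5))
desert_ip = CtMeasurement("ht29", "gene_desert", (30.8, 31.0, 30.9))
desert_in = CtMeasurement("ht29", "gene_desert", (24.9, 25.0, 24.8))

target = percent_input(promoter_ip, promoter_in, input_fraction=0.01)
control = percent_input(desert_ip, desert_in, input_fraction=0.01)
fold = fold_over_control(target, control)

print(f"promoter percent input : {target.percent_input:.3f}% ± {target.sd:.3f}")
print(f"gene desert control    : {control.percent_input:.4f}% ± {control.sd:.4f}")
print(f"fold over gene desert  : {fold:.1f}x   (>1 = specific binding)")

# --- RT-qPCR: target gene after knockdown, vs scrambled control ---
fold_expr = delta_delta_ct(
    ct_target_treated=CtMeasurement("kd", "CCNB1", (24.9, 25.1)),
    ct_ref_treated=CtMeasurement("kd", "GAPDH", (17.0, 17.1)),
    ct_target_control=CtMeasurement("scr", "CCNB1", (23.0, 23.2)),
    ct_ref_control=CtMeasurement("scr", "GAPDH", (17.1, 17.0)),
)
print(f"\nexpression after knockdown: {fold_expr:.2f}x of control")

t, p, stars = ttest_unpaired([24.9, 25.1, 25.0], [23.0, 23.2, 23.1])
print(f"unpaired t-test on raw Ct : t={t:.2f}, p={p:.2e} {stars}")
print("(stars: * p<0.05, ** p<0.01, *** p<0.001)")
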