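"""Translation-efficiency analysis on a simulated two-condition design.

Simulates FPKM tables for wild type vs a modification-deficient mutant
(two replicates each of mRNA input and ribosome footprints) in which genes
with tandem m2A-dependent codon runs lose half their translation efficiency.
The pipeline recovers the effect: per-bin median TE fold change near 0.5 for
tandem bins and near 1 for the rest, with the Kruskal-Wallis/rank-sum letter
display separating tandem bins from "others".
"""

from m2acodon import compare_groups, compute_te, te_fold_change
from m2acodon.simulate import SimConfig, simulate_expression, simulate_transcriptome
from m2acodon.te import call_de

cfg = SimConfig(
    n_genes=800,
    tandem_design={0: 500, 3: 100, 4: 100, 6: 100},
    delta={"others": 1.0, "run3": 0.5, "run4": 0.5, "run5plus": 0.5},
    seed=42,
)
_, truth = simulate_transcriptome(cfg)
expr = simulate_expression(truth, cfg)

te = compute_te(expr)
fc = te_fold_change(te)
bins = truth["tandem_bin"].reindex(fc.index)

print("median TE fold change (mutant / wild type) per tandem bin:")
print(fc.groupby(bins).median().round(3).to_string())

res = compare_groups(fc, bins)
print(f"\nKruskal-Wallis: H = {res.statistic:.1f}, p = {res.p_value:.2e}")
print("compact letter display (groups sharing no letter differ at adj. p<0.05):")
print("  ", res.letters)

de = call_de(expr)
print(f"\nmRNA-level DE calls (|FC|>2, adj. p<0.05, SNR>1): "
      f"{int(de['called'].sum())} of {len(de)} genes")
print("(the TE effect is translational; mRNA levels are unchanged, so few or "
      "no genes should be called)")
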