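"""Scan coding sequences for tandem runs of m2A-dependent codons.

Scans the four reporter insert sequences used in dual-luciferase assays
(S1-S3 carry natural tandem stretches of set codons; S4 is the negative
control) and then annotates a small simulated gene population into the
A-D groups that cross tandem status with codon-frequency decile.
"""

from m2acodon import (
    annotate_genes,
    census_tandem_genes,
    codon_frequency,
    cytosolic_codon_set,
    max_tandem_run,
    normalize_cds,
)
from m2acodon.simulate import SimConfig, simulate_transcriptome

cyto = cytosolic_codon_set()

inserts = {
    "S1": "CAACGTCGCCGT",
    "S2": "CAGCGTCAACAA",
    "S3": "CAACAGCGTCAACAACAG",
    "S4": "GTGGTGACAACA",
}
print("reporter inserts (max tandem run / set-codon frequency):")
for name, seq in inserts.items():
    gene = normalize_cds(seq, gene_id=name)
    print(f"  {name}: run {max_tandem_run(gene, cyto)}, "
          f"frequency {codon_frequency(gene, cyto):.2f}")

cfg = SimConfig(n_genes=400, tandem_design={0: 280, 3: 40, 4: 40, 6: 40},
                seed=11)
genes, _ = simulate_transcriptome(cfg, cyto)
annotations = annotate_genes(genes, cyto)
counts = {}
for a in annotations:
    counts[a.group] = counts.get(a.group, 0) + 1
print("\nsimulated population of 400 genes, group sizes:",
      dict(sorted(counts.items())))
print("(A: no tandem/low freq, B: tandem/low, C: no tandem/high, D: tandem/high)")

census = census_tandem_genes(genes, cyto, min_run=5)
print(f"\ngenes with a tandem run of 5 or more: {len(census)}")
print(census.head())
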