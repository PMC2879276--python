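"""Sex-biased expression of the relocated genes.

Classifies every (gene, species) cell of the packaged expression matrix by
sign and significance.  Despite the strong movement off the X — the pattern
selection explanations attribute to male-biased genes — the cohort is
dominated by female-biased (29 cells) and unbiased expression; male bias is
essentially confined to CG5029.
"""

from retromove import load_table2, summarize_expression

table2 = load_table2()
s = summarize_expression(table2)
print(f"female-biased cells : {s['female_cells']}")
print(f"male-biased cells   : {s['male_cells']} "
      f"({s['male_cells_excluding']['count']} outside "
      f"{','.join(s['male_cells_excluding']['genes'])})")
print("CG5029 male fraction:",
      s["male_fraction_per_outlier"]["CG5029"])
print(f"genes with the same class in every assayed species "
      f"({len(s['consistent_genes'])}/{s['n_genes']}):")
for gene, cls in s["consistent_genes"].items():
    print(f"  {gene:>8}  {cls}")
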