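"""Preranked GSEA and leading-edge multiplicity.

Genes are ranked by signed -log10(p) from the DE stage; each gene set gets a
running-sum enrichment score, a permutation-normalised NES and a BH-adjusted
p-value.  Genes in the leading edge of two or more significant sets are the
first evidence arm of the final signature.
"""

from qsig import dge, enrichment, simdata

counts, truth = simdata.simulate_counts(
    n_genes=1500, de_fraction=0.05, lfc_magnitude=2.5, dispersion=0.1,
    seed=11)
signal = [g for g in truth.de_genes if truth.log2_fc[g] > 0][:20]
collection = simdata.simulate_genesets(
    universe=list(counts.index), n_sets=20, set_size_range=(10, 30),
    planted_sets=5, signal_genes=signal, seed=12)

de = dge.test_de_threshold(counts, truth.sample_meta, theta=0.0)
ranked = enrichment.rank_genes(de, mode="signed_logp")
res = enrichment.gsea(ranked, collection, n_perm=1000, seed=13)

print(res[["ES", "NES", "pval", "padj", "size"]].round(4).head(8))
print(f"{int(res['significant'].sum())} sets significant at FDR 5% "
      "(the 5 planted sets should be among them)")

multiplicity = enrichment.leading_edge_multiplicity(res, min_sets=2)
hits = set(multiplicity.index) & set(signal)
print(f"{len(multiplicity)} genes appear in >= 2 significant leading edges; "
      f"{len(hits)}/{len(signal)} are planted signal genes")
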