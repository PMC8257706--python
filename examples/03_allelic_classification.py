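"""Classify genes as maternally/paternally expressed and call imprinting loss.

Genes with mean maternal ratio mat/(mat+pat) <= 0.33 are paternally
expressed, >= 0.67 maternally expressed. Imbalance is tested by an exact
two-sided proportion test on pooled raw counts with Benjamini-Hochberg
correction. Wild-type monoallelic genes are then compared with the mutant
condition to call loss of imprinting.
"""

import hybrid_ase as ha

cfg = ha.SimConfig(
    seed=3, n_genes=20, chrom_length_bp=120_000,
    class_proportions=(("maternal", 0.25), ("paternal", 0.25), ("biallelic", 0.5)),
    nb_mean_log2_loc=8.0, loss_fraction=1.0,
)
bulk, maternal, paternal, manifest = ha.simulate_counts(cfg)
sf = ha.estimate_size_factors(bulk)
norm_mat, norm_pat = ha.normalize_allelic_counts(maternal, paternal, sf)

wt = ha.compute_ase(
    norm_mat.counts, norm_pat.counts, maternal.counts, paternal.counts,
    ["wt_1", "wt_2"], require_significance=True,
)
mut = ha.compute_ase(
    norm_mat.counts, norm_pat.counts, maternal.counts, paternal.counts,
    ["mut_1", "mut_2"],
)

print(f"{'gene':10s} {'truth':10s} {'WT ratio':>9s} {'q':>9s} {'WT call':10s} {'transition'}")
for gene, row in manifest.genes.iterrows():
    r = wt[gene]
    call = r.allelic_class
    transition = ""
    if call in (ha.AllelicClass.MATERNAL, ha.AllelicClass.PATERNAL):
        transition = ha.compare_conditions(r, mut[gene]).transition.value
    print(
        f"{gene:10s} {row['class']:10s} {r.mean_ratio:9.3f} {r.q_value:9.2e} "
        f"{call.value:10s} {transition}"
    )
print(
    "\nevery simulated imprinted gene loses its bias in the mutant "
    "(true maternal fraction reverts to 0.5), so transitions read 'Biallelic'"
)
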