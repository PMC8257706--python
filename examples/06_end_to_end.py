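"""Full imprinting-loss analysis from simulated alignments to the summary table.

Simulates an F1-hybrid experiment (2 wild-type + 2 mutant replicates) in
which ten imprinted genes revert to biallelic expression in the mutant,
then runs the complete pipeline: dedup, allele splitting, counting, size
factors, allelic filters, classification, condition comparison, NB Wald
differential expression, and the integrated per-gene summary.
"""

import numpy as np
import pandas as pd

import hybrid_ase as ha

cfg = ha.SimConfig(
    seed=6, n_chroms=2, chrom_length_bp=400_000, n_genes=30,
    nb_mean_log2_loc=float(np.log2(300.0)), nb_mean_log2_scale=0.0,
    nb_dispersion=0.05, frac_de=0.0, loss_fraction=1.0,
)
rng = cfg.rng()
reference, snps = ha.simulate_genomes(cfg, rng)
genes = ha.place_genes(cfg, rng)
truth = ha.assign_gene_truth(cfg, genes, rng)
classes = ["maternal"] * 5 + ["paternal"] * 5 + ["biallelic"] * 20
truth["class"] = classes
truth["rho_wt"] = [cfg.rho_for(c) for c in classes]
truth["rho_mut"] = np.where(truth["class"] != "biallelic", 0.5, truth["rho_wt"])
lfc = np.zeros(30)
lfc[[0, 1, 5, 6]] = 2.0   # imprinted genes up-regulated upon loss
lfc[[2, 7]] = -2.0        # imprinted genes down-regulated
truth["log2_fc"] = lfc
bulk_t, mat_t, pat_t, _ = ha.simulate_counts(cfg, truth, rng)

index = ha.SnpIndex(snps)
bulk_cols, mat_cols, pat_cols = [], [], []
for sample in cfg.sample_ids:
    frag_counts = pd.DataFrame({"mat": mat_t.counts[sample], "pat": pat_t.counts[sample]})
    records, _ = ha.simulate_alignments(cfg, reference, snps, genes, frag_counts, rng, sample_id=sample)
    deduped = list(ha.dedupe_alignments(records))
    g1, g2, _ = ha.split_alignments(deduped, index)
    bulk_cols.append(ha.count_fragments(ha.pair_fragments(deduped), genes, sample, "BULK"))
    mat_cols.append(ha.count_fragments(ha.pair_fragments(g2), genes, sample, "MATERNAL"))
    pat_cols.append(ha.count_fragments(ha.pair_fragments(g1), genes, sample, "PATERNAL"))

result = ha.run_ase_workflow(
    ha.combine_samples(bulk_cols),
    ha.combine_samples(mat_cols),
    ha.combine_samples(pat_cols),
    ["wt_1", "wt_2"],
    ["mut_1", "mut_2"],
)

print("size factors:", result.size_factors.round(3).to_dict())
print(f"{len(result.tested_genes)} genes pass the allelic filters; "
      f"{len(result.integration)} are imprinted in wild-type\n")
table = ha.integration_table(result.integration).drop(columns="domain")
print(table.to_string())
print(
    "\neach row joins the wild-type allelic call, the mutant transition and "
    "the expression change; all ten planted imprinted genes read 'Biallelic' "
    "in the mutant with their planted DE direction"
)
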