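"""Discover novel miRNAs from unannotated tag loci.

Excises candidate precursor windows around each unannotated genome hit,
folds them with ViennaRNA, measures the miRNA/miRNA* duplex and applies
the standard plant candidate criteria (stem-loop fold, mature on one
arm, < 6 duplex mismatches, intact star, MFE <= -18 kcal/mol,
MFEI >= 0.85, 30-70% A+U, >= 16 duplex pairs, bulge/asymmetry <= 4).
"""

from mirseed import annotation, cleaning, hairpin
from mirseed.simulate import SimulationConfig, simulate_experiment

config = SimulationConfig(n_planted_mirnas=8, read_depth=10_000, seed=42)
out = simulate_experiment(config)
surv_c, _ = cleaning.clean_reads(out.reads_control, config.adapter_5p, config.adapter_3p)
surv_t, _ = cleaning.clean_reads(out.reads_treatment, config.adapter_5p, config.adapter_3p)
tags = cleaning.collapse_unique(surv_c, surv_t)

records, hits, high_copy = annotation.annotate(
    tags, out.genome, mature_ref=out.mature_ref,
    ncrna_refs=out.ncrna_refs, gene_features=out.gene_features,
)
search = {
    r.tag_id: hits[r.tag_id]
    for r in records
    if r.category == "unannotated" and r.tag_id in hits and r.tag_id not in high_copy
}
counts = {t.sequence: (t.count_control, t.count_treatment) for t in tags}
predictions = hairpin.predict_novel(out.genome, search, counts)

print(f"search space: {len(search)} unannotated mapped tags")
print(f"accepted novel miRNAs: {len(predictions)}\n")
for p in predictions:
    print(f"{p.chrom}:{p.start}-{p.end} ({p.strand})  mature {p.mature}")
    print(f"  MFE {p.fold.mfe:.1f} kcal/mol  MFEI {p.mfei:.2f}  A+U {p.au_content:.2f}"
          f"  reads {p.count_control}/{p.count_treatment}")
    print(f"  {p.fold.structure}")

planted_novel = set(out.truth[(out.truth.locus_class == "miRNA") & ~out.truth.known].tag_seq)
recovered = planted_novel & {p.mature for p in predictions}
print(f"\nplanted novel hairpins recovered: {len(recovered)}/{len(planted_novel)}")
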