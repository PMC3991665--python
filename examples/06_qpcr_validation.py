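"""ddCt quantification of qPCR Ct tables and cross-method concordance.

Builds a noiseless Ct table for one miRNA and its target gene (ef1a as
the internal reference, 3 biological x 2 technical replicates), inverts
it with 2^-ddCt, and checks whether the miRNA's qPCR direction matches
its sequencing call and opposes its target — the validation pattern
used to nominate stress-responsive miRNAs.
"""

import math

import pandas as pd

from mirseed.qpcr import concordance_report, relative_expression


def ct_rows(gene, fold):
    rows = []
    shift = -math.log2(fold)
    for rep in range(3):
        for cond, d in (("control", 0.0), ("treatment", shift)):
            for tech in range(2):
                rows.append((gene, cond, rep, tech, 25.0 + d))
    return rows


rows = ct_rows("miR-a", 0.3) + ct_rows("GENE-1", 2.5)
for rep in range(3):
    for cond in ("control", "treatment"):
        for tech in range(2):
            rows.append(("ef1a", cond, rep, tech, 20.0))
ct = pd.DataFrame(rows, columns=["target_id", "condition", "bio_rep", "tech_rep", "ct"])

rel = relative_expression(ct)
print(rel.to_string(index=False))
# fold_change is 2^-ddCt, mean over biological replicates

report = concordance_report(
    mirna_qpcr=rel[rel.target_id == "miR-a"],
    target_qpcr=rel[rel.target_id == "GENE-1"],
    sequencing_calls=pd.DataFrame({"mirna_id": ["miR-a"], "call": ["down"]}),
    pairs=pd.DataFrame({"mirna_id": ["miR-a"], "target_id": ["GENE-1"]}),
)
print()
print(report.T.to_string(header=False))
# both flags true: the miRNA is a validated candidate (down by both
# methods, its target up)
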