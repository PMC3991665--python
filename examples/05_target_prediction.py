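"""Score miRNA target sites on a small engineered transcriptome.

Penalty scoring of the antiparallel duplex: mismatch 1, G:U wobble 0.5,
gap 2, doubled in the seed (miRNA positions 2-13).  Sites with
expectation <= 3.0 are kept, and a mismatch at positions 9-11 switches
the predicted mode from cleavage to translational inhibition.  UPE is
the energy to unpair the site (+17/-13 nt flanks) in its transcript.
"""

import numpy as np

from mirseed._seq import revcomp
from mirseed.targets import scan_transcripts, score_site

mirna = "TGGAGCTCCCTTCATTCCAAT"
perfect_site = revcomp(mirna)

rng = np.random.default_rng(0)
background = "".join(rng.choice(list("ACGT"), 400))
mismatch_site = list(perfect_site)
mismatch_site[len(mirna) - 10] = "A"  # pairs miRNA position 10
transcripts = {
    "tx-perfect": background[:200] + perfect_site + background[200:],
    "tx-central-mismatch": background[:200] + "".join(mismatch_site) + background[200:],
}

exp, alignment, kinds = score_site(mirna, perfect_site)
print(f"perfect site expectation: {exp}")
print(alignment)

for tx_id, seq in transcripts.items():
    sites = scan_transcripts("miR-x", mirna, {tx_id: seq})
    for s in sites:
        print(
            f"\n{tx_id}: site {s.start}-{s.end}, expectation {s.expectation},"
            f" mode {s.mode}, UPE {s.upe:.1f} kcal/mol"
        )
# the central mismatch costs 2 (doubled: position 10 is in the seed) and
# flips the predicted mode to translational inhibition
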