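# Methods

`mirseed` re-implements, as a tested library, the analysis chain of a
two-condition plant small-RNA sequencing study: one sequencing library
per condition (control vs osmotic/PEG "drought" treatment), cleaning of
raw reads, annotation of unique tags, discovery of known and novel
miRNAs, exact count-based differential expression, complementarity-based
target prediction, and ddCt arithmetic for qPCR validation. Every stage
is driven by a simulator that plants the ground truth it is later asked
to recover, so the pipeline's guarantees are stated and tested as
recovery properties rather than as agreement with any particular
dataset.

## The simulator and what it does (not) emulate

`simulate.simulate_experiment` builds a single-chromosome random genome
(default 100 kb, GC 0.5) with non-overlapping planted loci:

- **pre-miRNA hairpins** — mature (20–23 nt, 21 nt modal) + loop +
  reverse-complement star, inserted on a random strand. Construction is
  by design, not rejection sampling: each planted window is evaluated
  with the same criteria function the predictor uses, and loops/flank
  context are re-drawn (bounded retries) until it passes, which makes
  the generator–evaluator round trip exact and runtime bounded.
  Matures are capped at 23 nt because a designed perfect stem gives a
  star of the same length and the prediction criteria bound the star to
  20–23 nt. A configurable fraction of planted miRNAs is emitted as the
  "known" mature reference; the rest are the novel-discovery truth.
- **rRNA/tRNA/snoRNA/snRNA loci**, whose sequences are exported as
  GenBank-like and Rfam-like reference pools; **exon/intron** intervals
  exported as gene features; and unstructured **decoy** loci that remain
  unannotated and test the discovery specificity.

Each expressing locus gets one fixed sequencing tag and a log-normal
base abundance; treatment abundances are multiplied by the configured
fold changes. Per-locus counts are independent Poisson draws around
those abundances. The earlier multinomial design (fixed library size)
was dropped because renormalizing per-library weights distorts planted
fold changes compositionally; with Poisson counts a planted 4-fold
change is 4-fold in expectation, and the library size is the expected,
not exact, depth.

Reads are insert + 3′ adapter, padded with random bases to 50 nt at
Phred 40, with the study protocol's adapter sequences as defaults
(U→T normalized; all sequence handling is in DNA space). Contaminant
reads are injected per cleaning class at configured fractions, each
constructed (and verified against the cleaning rules at build time) to
fail exactly its intended rule. The simulator does **not** model
position-dependent error profiles, quality decay, ligation bias, or
multi-isoform miRNA loci; a uniform substitution rate is available but
defaults to 0. Passing recovery tests therefore demonstrate correctness
of the pipeline's logic under idealized sequencing, not robustness to
real-world noise.

## Read cleaning

Seven steps, each read assigned its first failing rule so the fates
partition the input exactly: (1) low quality, (2) 5′ adapter
contaminant, (3) no 3′ adapter, (4) no insert, (5) polyA, (6) insert
outside 18–30 nt, (7) the length-distribution summary. Published
descriptions of such cascades leave three definitions open; ours are
configurable (`CleaningParams`): low quality = >20% of bases below
Q10; the 3′ adapter is located by the leftmost ungapped match allowing
1 mismatch per 10 matched bases, with at least 6 matched bases; polyA =
insert ≥80% A or containing a run of ≥10 A. Inserts longer than 30 nt
are counted under rule 6 (the analysis window is 18–30 nt).

## Annotation

Genome mapping is exact-match on both strands (18-mer seed index + full
verification); tags with more than 20 genomic copies are flagged and
excluded from novel-miRNA candidacy. Known miRNAs require perfect
identity with a reference mature or exact containment in a reference
precursor — a single mismatch disqualifies. Exon/intron assignment
requires ≥1 nt same-strand overlap of a genomic hit. siRNA candidate
pairs are 22–24 nt tags on opposite strands of one locus offset so each
strand's 3′ end overhangs by exactly 2 nt. Category conflicts resolve
by the fixed priority rRNA etc. (GenBank > Rfam) > known miRNA >
repeat > exon > intron; the repeat level is skipped unless repeat
intervals are supplied. Resolution is a pure function of the category
set.

## Novel miRNA prediction

For each unannotated genome-mapped tag, candidate windows place the tag
on either arm with star-side extensions up to `max_space + flank`
(several steps; the exact grid does not matter because of trimming,
below) and a 20 nt flank on the tag side. Each window is folded
(ViennaRNA 2.x MFE fold; the engine sits behind a minimal
sequence → structure + energy contract), then trimmed to the outermost
base pair enclosing the miRNA/miRNA* duplex plus the flank and
refolded, iterating to a fixed point. This delimitation makes the
evaluated precursor independent of the enumerated window size and is
what lets the generator verify compliance at the planted window while
the predictor approaches it from arbitrary excisions.

Duplex metrics come from the dot-bracket pair table: star = the
pairing-partner span of the mature (the strand Dicer would release;
the 2-nt 3′ overhang convention orients spacing and the reported star);
mismatches = unpaired mature positions; bulge = longest unpaired run on
either strand; asymmetry = |unpaired(mature) − unpaired(star)|. A
mature that pairs into itself or has partners on both sides straddles
the terminal loop and is rejected.

Acceptance requires all of: stem-loop formed with the mature on one
arm; mismatches < 6; star intact (no loop crossing, no unpaired run
beyond the bulge cap); MFE ≤ −18 kcal/mol; MFEI ≥ 0.85;
A+U ∈ [0.30, 0.70]; ≥ 16 duplex pairs; bulge ≤ 4; asymmetry ≤ 4;
spacing ≤ 300 nt; mature 18–25 nt; star 20–23 nt. MFEI =
(|MFE|/length × 100)/GC% — the standard index; its cutoff of 0.85
follows common plant-miRNA practice and is configurable. An optional
conservation filter (≤ 4 substitutions against a supplied set of known
plant matures) is off by default since it restricts, rather than
defines, novelty. Overlapping accepted precursors deduplicate to the
lowest MFE, ties to the leftmost. Acceptance is monotone: tightening
any threshold can only remove predictions.

## Differential expression

Counts are normalized as TPM = count/clean-library-total × 10⁶, so the
per-library TPMs sum to 10⁶ exactly. Fold change is
log2(treatment/control) with a 0.01-TPM stand-in for zeros (used for
ratios only; tags absent from both libraries are reported flat with
p = 1, never as pseudo-count artifacts). Regulation is called at
2-fold.

Significance is the classic exact statistic for two libraries of known
depths: conditional on x, the second count follows
p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1)), a negative
binomial (exposed as `count_probability`). For the reported p-value we
condition on the pair total instead — y | x+y ~ Binomial(x+y,
N2/(N1+N2)), the same exact family (the conditional pmf above equals
this binomial up to a factor constant in y) — and sum the
minimum-likelihood two-sided tail. The reason is symmetry: the
y-given-x tail changes by up to ~0.06 in p (a factor ~2 for small p)
when the libraries are swapped, whereas the total-conditioned tail is
exactly swap-invariant, which we hold as an invariant of the module.
Tail sums use the unimodality of the pmf: the rejection region is the
complement of a central interval whose far boundary is found by binary
search on the log-pmf (stable to counts ~10⁷). No multiple-testing
correction is applied by default (selection is fold-change-based);
Benjamini–Hochberg q-values are available as an option.

## Target prediction

Plant-style complementarity scoring of the antiparallel miRNA/mRNA
duplex: mismatch 1, G:U wobble 0.5, gap 2, doubled at miRNA positions
2–13 (the seed); the total is the site's expectation, 0 for a perfect
reverse complement, cutoff 3.0. At most one gap per duplex; scanning
tries every window at miRNA length ±1 with exhaustive single-gap
placement and deduplicates overlapping candidates to the best score. A
mismatch or gap (not a wobble) at miRNA positions 9–11 classifies the
site as translational inhibition, else cleavage. Site accessibility
(UPE) is the difference between the constrained (site plus 17 nt
upstream/13 nt downstream forced single-stranded) and unconstrained
ensemble free energies of a ±150 nt local context, computed with the
folding engine's partition function; sites with UPE ≥ 25 kcal/mol are
filtered when the engine is present, and retained with a warning when
it is not.

## qPCR quantification

dCt = Ct(gene) − Ct(reference) per condition and biological replicate,
technical replicates averaged first; ddCt = dCt(treatment) −
dCt(control) per biological replicate; fold = 2^−ddCt, reported as
mean ± SD (ddof = 1) over replicates. Amplification efficiency is
fixed at 100%. Noiseless synthetic tables invert exactly
(log2(fold) = −ddCt is an identity). The concordance report flags, per
miRNA: agreement of the qPCR direction with the sequencing call, and
anticorrelation with its target gene; candidates require both.

## Numerical and design notes

- Coordinates are 0-based, half-open, strands '+'/'−'; sequences are
  DNA internally (U→T on input, T→U only at the folding boundary).
- Determinism: every stochastic step flows from one integer seed
  through `numpy.random.default_rng`; identical configs give
  byte-identical libraries, and folding is deterministic, so the whole
  pipeline replays exactly.
- Degenerate inputs fail loudly: empty genomes, duplicate reference
  ids, features outside the genome, missing reference Ct rows, and
  unbuildable hairpins raise with diagnostics (the failing criteria are
  named) rather than being skipped.
- Default problem sizes in the tests and the reproduction script —
  100 kb genome, 10⁴–3×10⁴ reads per library, 500-row DE panels, 2,000
  null rows — were chosen as the smallest scales at which the binomial
  sampling error of each recovery property is comfortably below its
  asserted margin.

## Known limitations

- Exact-match mapping only; a single sequencing error orphans a tag
  (real studies tolerate mismatches via heuristic aligners, which are
  out of scope here).
- One library per condition: the exact count test captures sampling
  noise only, not biological variance; with replicates a dispersion
  model would be required.
- The scoring weights of the target module follow the published scheme
  of the standard plant target server; its exact UPE protocol is not
  published at implementation level, so accessibility values are
  comparable within this package, not against the server's output.
- The discovery stage evaluates one mature placement per tag hit; it
  does not enumerate alternative Dicer registers or isomiRs.
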