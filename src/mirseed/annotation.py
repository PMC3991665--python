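"""Tag annotation: genome mapping, known-miRNA matching, ncRNA/exon/intron
classification, siRNA duplex detection and single-category resolution.

A clean tag can match several reference classes; the pipeline resolves
each tag to exactly one category with the fixed priority

    rRNA etc. (GenBank > Rfam) > known miRNA > repeat > exon > intron

with siRNA-candidate and unannotated below the chain.  Unannotated
genome-mapped tags form the novel-miRNA search space.

Genome mapping is exact-match on both strands (a seed-and-verify scan;
no heuristic alignment), with tags present at more than ``max_copies``
genomic loci flagged and excluded from novel-miRNA candidacy.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._seq import revcomp, to_dna
from .cleaning import CleanTag

__all__ = [
    "GenomeHit",
    "AnnotationRecord",
    "GenomeIndex",
    "PRIORITY_ORDER",
    "map_to_genome",
    "match_known_mirnas",
    "classify_other",
    "identify_sirna_candidates",
    "resolve_priority",
    "annotate",
]

#: Category names, highest priority first.  'siRNA_candidate' and
#: 'unannotated' never compete with the chain: they apply only to tags
#: matching none of the reference classes.
PRIORITY_ORDER = [
    "rRNA_etc_genbank",
    "rRNA_etc_rfam",
    "known_miRNA",
    "repeat",
    "exon",
    "intron",
]

SIRNA_MIN_LEN = 22
SIRNA_MAX_LEN = 24
SIRNA_OVERHANG = 2


@dataclass(frozen=True)
class GenomeHit:
    tag_id: str
    chrom: str
    start: int  # 0-based, half-open
    end: int
    strand: str  # '+' or '-'
    copy_number: int = 1  # total genomic copies of the tag


@dataclass(frozen=True)
class AnnotationRecord:
    tag_id: str
    category: str
    evidence: str = ""


@dataclass(frozen=True)
class GeneFeature:
    """Exon or intron interval from a gene annotation."""

    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # 'exon' | 'intron'
    gene_id: str = ""


class GenomeIndex:
    """Seed-and-verify exact matcher over a genome FASTA dict.

    Indexes every ``seed``-length word of the forward strand; a query is
    located by looking up its first seed and verifying the full sequence,
    on both strands.
    """

    def __init__(self, genome: Mapping[str, str], seed: int = 18):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome")
        self.seed = seed
        self.genome = {name: to_dna(seq) for name, seq in genome.items()}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.genome.items():
            for i in range(0, len(seq) - seed + 1):
                self._index[seq[i : i + seed]].append((name, i))

    def find(self, query: str) -> list[tuple[str, int, str]]:
        """All exact occurrences of ``query`` as (chrom, start, strand)."""
        query = to_dna(query)
        if len(query) < self.seed:
            raise ValueError(f"query shorter than seed length {self.seed}")
        hits = []
        for strand, q in (("+", query), ("-", revcomp(query))):
            for name, i in self._index.get(q[: self.seed], ()):
                if self.genome[name][i : i + len(q)] == q:
                    hits.append((name, i, strand))
        return sorted(set(hits))


def map_to_genome(
    tags: Sequence[CleanTag],
    genome: Mapping[str, str] | GenomeIndex,
    max_copies: int = 20,
) -> tuple[dict[str, list[GenomeHit]], set[str]]:
    """Exact-match all tags to the genome on both strands.

    Returns (hits per tag id, ids of tags exceeding ``max_copies`` genomic
    copies).  High-copy tags keep their hits for annotation but are
    excluded from novel-miRNA candidacy.  Tag ids are the tag sequences.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    hits: dict[str, list[GenomeHit]] = {}
    high_copy: set[str] = set()
    for tag in tags:
        found = index.find(tag.sequence)
        if not found:
            continue
        n = len(found)
        hits[tag.sequence] = [
            GenomeHit(tag.sequence, chrom, start, start + len(tag.sequence), strand, n)
            for chrom, start, strand in found
        ]
        if n > max_copies:
            high_copy.add(tag.sequence)
    return hits, high_copy


def match_known_mirnas(
    tags: Sequence[CleanTag],
    mature_ref: Mapping[str, str],
    precursor_ref: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Assign tags to known miRNAs by perfect sequence identity.

    A tag is a known miRNA iff (T/U-normalized) it equals a reference
    mature sequence, or is an exact substring of a reference precursor.
    Returns {tag sequence: reference id}.  Near-matches (even a single
    mismatch) are never assigned.
    """
    if not mature_ref and not precursor_ref:
        raise ValueError("empty known-miRNA reference")
    ids = list(mature_ref) + list(precursor_ref or {})
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate ids in miRNA reference")
    by_seq = {to_dna(seq): rid for rid, seq in mature_ref.items()}
    precursors = {rid: to_dna(seq) for rid, seq in (precursor_ref or {}).items()}
    assigned: dict[str, str] = {}
    for tag in tags:
        seq = to_dna(tag.sequence)
        if seq in by_seq:
            assigned[tag.sequence] = by_seq[seq]
            continue
        for rid, pre in precursors.items():
            if seq in pre:
                assigned[tag.sequence] = rid
                break
    return assigned


def classify_other(
    tags: Sequence[CleanTag],
    hits: Mapping[str, list[GenomeHit]],
    ncrna_refs: Mapping[str, Mapping[str, str]] | None = None,
    gene_features: Sequence[GeneFeature] = (),
    repeat_intervals: Sequence[tuple[str, int, int]] = (),
    genome_lengths: Mapping[str, int] | None = None,
) -> dict[str, set[str]]:
    """Candidate category sets per tag (before priority resolution).

    ``ncrna_refs`` maps source name ('genbank' or 'rfam') to {id: sequence}
    covering rRNA/tRNA/snRNA/snoRNA pools; a tag matches when it is an
    exact substring of any reference sequence.  Exon/intron categories
    come from same-strand interval overlap (>= 1 nt) of the tag's genomic
    hits with gene features; 'repeat' from overlap with repeat intervals
    (strand-agnostic).
    """
    if genome_lengths:
        for feat in gene_features:
            limit = genome_lengths.get(feat.chrom)
            if limit is not None and (feat.start < 0 or feat.end > limit):
                raise ValueError(
                    f"feature {feat.gene_id or feat.kind} outside {feat.chrom}"
                )
    source_category = {"genbank": "rRNA_etc_genbank", "rfam": "rRNA_etc_rfam"}
    categories: dict[str, set[str]] = {tag.sequence: set() for tag in tags}

    for source, refs in (ncrna_refs or {}).items():
        cat = source_category[source.lower()]
        pool = [to_dna(s) for s in refs.values()]
        for tag in tags:
            seq = to_dna(tag.sequence)
            if any(seq in ref or revcomp(seq) in ref for ref in pool):
                categories[tag.sequence].add(cat)

    by_chrom: dict[str, list[GeneFeature]] = defaultdict(list)
    for feat in gene_features:
        by_chrom[feat.chrom].append(feat)
    for tag in tags:
        for hit in hits.get(tag.sequence, ()):
            for feat in by_chrom.get(hit.chrom, ()):
                if feat.strand == hit.strand and hit.start < feat.end and feat.start < hit.end:
                    categories[tag.sequence].add(feat.kind)
            for chrom, start, end in repeat_intervals:
                if chrom == hit.chrom and hit.start < end and start < hit.end:
                    categories[tag.sequence].add("repeat")
    return categories


def identify_sirna_candidates(
    tags: Sequence[CleanTag], hits: Mapping[str, list[GenomeHit]]
) -> list[tuple[GenomeHit, GenomeHit]]:
    """Pairs of 22-24 nt tags forming genomic duplexes with 2-nt 3' overhangs.

    Two tags qualify when they map to opposite strands of the same locus
    such that each strand's 3' end extends exactly 2 nt past the other's
    5' end: for a plus-strand hit [s1, e1) and minus-strand hit [s2, e2),
    s1 = s2 + 2 and e1 = e2 + 2.
    """
    plus, minus = [], []
    for tag in tags:
        if not (SIRNA_MIN_LEN <= len(tag.sequence) <= SIRNA_MAX_LEN):
            continue
        for hit in hits.get(tag.sequence, ()):
            (plus if hit.strand == "+" else minus).append(hit)
    pairs = []
    minus_by_key = defaultdict(list)
    for hit in minus:
        minus_by_key[(hit.chrom, hit.start, hit.end)].append(hit)
    for p in plus:
        for m in minus_by_key.get((p.chrom, p.start - SIRNA_OVERHANG, p.end - SIRNA_OVERHANG), ()):
            pairs.append((p, m))
    return pairs


def resolve_priority(category_sets: Mapping[str, set[str]]) -> list[AnnotationRecord]:
    """One category per tag by the fixed priority order.

    A pure function of each tag's category set: the highest-priority
    member wins; an empty set resolves to 'unannotated'.  Unknown category
    names raise.
    """
    records = []
    for tag_id, cats in category_sets.items():
        unknown = cats - set(PRIORITY_ORDER)
        if unknown:
            raise ValueError(f"unknown categories for {tag_id}: {sorted(unknown)}")
        chosen = next((c for c in PRIORITY_ORDER if c in cats), "unannotated")
        records.append(AnnotationRecord(tag_id, chosen))
    return records


def annotate(
    tags: Sequence[CleanTag],
    genome: Mapping[str, str] | GenomeIndex,
    mature_ref: Mapping[str, str] | None = None,
    precursor_ref: Mapping[str, str] | None = None,
    ncrna_refs: Mapping[str, Mapping[str, str]] | None = None,
    gene_features: Sequence[GeneFeature] = (),
    repeat_intervals: Sequence[tuple[str, int, int]] = (),
    max_copies: int = 20,
) -> tuple[list[AnnotationRecord], dict[str, list[GenomeHit]], set[str]]:
    """Full annotation pass: map, classify, resolve.

    Returns (records, genome hits per tag, high-copy tag ids).  The
    novel-miRNA search space is the 'unannotated' records whose tags have
    genome hits and are not high-copy.
    """
    hits, high_copy = map_to_genome(tags, genome, max_copies=max_copies)
    categories = classify_other(
        tags, hits, ncrna_refs=ncrna_refs, gene_features=gene_features,
        repeat_intervals=repeat_intervals,
    )
    if mature_ref or precursor_ref:
        for tag_seq in match_known_mirnas(tags, mature_ref or {}, precursor_ref):
            categories[tag_seq].add("known_miRNA")
    records = resolve_priority(categories)
    return records, hits, high_copy
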