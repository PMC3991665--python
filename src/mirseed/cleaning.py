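"""Raw small-RNA read cleaning: the 7-step elimination cascade.

Raw sequencer reads are insert + 3' adapter (+ downstream bases).  Each
read is assigned exactly one fate — the first rule it fails:

  1. low quality (more than ``max_low_frac`` of bases below ``min_phred``)
  2. 5' adapter contaminant (read begins with the 5' adapter)
  3. no 3' adapter found
  4. no insert (adapter dimer: the 3' adapter starts at position 0)
  5. polyA insert
  6. insert outside the 18-30 nt analysis window

Survivors are trimmed to their insert.  Step 7 of the cascade is the
length-distribution summary carried in the report.  The partition is
exact: raw total = sum of per-rule removals + clean total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from ._seq import to_dna

__all__ = [
    "FastqRead",
    "CleanTag",
    "CleaningReport",
    "CleaningParams",
    "clean_reads",
    "collapse_unique",
    "length_distribution",
]

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30

RULE_NAMES = {
    1: "low_quality",
    2: "adapter5_contaminant",
    3: "no_adapter3",
    4: "no_insert",
    5: "polyA",
    6: "length_window",
}


class FastqRead(NamedTuple):
    read_id: str
    sequence: str
    quality: str  # Sanger Phred+33


@dataclass(frozen=True)
class CleanTag:
    """A unique clean small-RNA sequence with per-library read counts."""

    sequence: str
    count_control: int = 0
    count_treatment: int = 0

    def __post_init__(self) -> None:
        if not (MIN_TAG_LEN <= len(self.sequence) <= MAX_TAG_LEN):
            raise ValueError(f"tag length {len(self.sequence)} outside [{MIN_TAG_LEN}, {MAX_TAG_LEN}]")
        if self.count_control < 0 or self.count_treatment < 0:
            raise ValueError("negative tag count")
        if self.count_control == 0 and self.count_treatment == 0:
            raise ValueError("tag with zero counts in both libraries")

    @property
    def total(self) -> int:
        return self.count_control + self.count_treatment


@dataclass
class CleaningReport:
    raw_total: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {name: 0 for name in RULE_NAMES.values()}
    )
    clean_total: int = 0
    length_histogram: dict[int, int] = field(
        default_factory=lambda: {n: 0 for n in range(MIN_TAG_LEN, MAX_TAG_LEN + 1)}
    )

    def check_partition(self) -> None:
        if self.raw_total != sum(self.removed.values()) + self.clean_total:
            raise AssertionError("cleaning fates do not partition the raw reads")
        if sum(self.length_histogram.values()) != self.clean_total:
            raise AssertionError("length histogram does not sum to the clean total")


@dataclass(frozen=True)
class CleaningParams:
    """Tunable definitions the cascade's published description leaves open."""

    min_phred: int = 10          # base counts as low-quality below this
    max_low_frac: float = 0.20   # rule 1 fires above this fraction
    adapter_mismatch_per_10nt: int = 1
    min_adapter_match: int = 6   # shortest 3' adapter prefix accepted at the read end
    polya_fraction: float = 0.80
    polya_run: int = 10
    min_len: int = MIN_TAG_LEN
    max_len: int = MAX_TAG_LEN
    phred_offset: int = 33


def _is_low_quality(qual: str, params: CleaningParams) -> bool:
    if not qual:
        return True
    low = sum(1 for q in qual if ord(q) - params.phred_offset < params.min_phred)
    return low / len(qual) > params.max_low_frac


def _matches_prefix(read: str, adapter: str, params: CleaningParams) -> bool:
    """Does the read start with (a prefix of) the adapter?"""
    n = min(len(read), len(adapter))
    if n < params.min_adapter_match:
        return False
    mism = sum(1 for a, b in zip(read[:n], adapter[:n]) if a != b)
    return mism <= (n // 10) * params.adapter_mismatch_per_10nt


def _find_adapter3(read: str, adapter: str, params: CleaningParams) -> int | None:
    """Leftmost start of the 3' adapter in the read, or None.

    The adapter may run off the read end; a truncated match must still
    cover at least ``min_adapter_match`` bases.  Mismatch tolerance is one
    per 10 matched bases (ungapped).
    """
    for i in range(0, len(read) - params.min_adapter_match + 1):
        n = min(len(adapter), len(read) - i)
        mism = 0
        allowed = (n // 10) * params.adapter_mismatch_per_10nt
        ok = True
        for a, b in zip(read[i : i + n], adapter[:n]):
            if a != b:
                mism += 1
                if mism > allowed:
                    ok = False
                    break
        if ok:
            return i
    return None


def _is_polya(insert: str, params: CleaningParams) -> bool:
    if not insert:
        return False
    if insert.count("A") / len(insert) >= params.polya_fraction:
        return True
    return "A" * params.polya_run in insert


def clean_reads(
    reads: Iterable[FastqRead],
    adapter_5p: str,
    adapter_3p: str,
    params: CleaningParams | None = None,
) -> tuple[list[str], CleaningReport]:
    """Run the elimination cascade; return surviving inserts and the report.

    Adapters may be given as RNA or DNA; they are normalized to DNA.
    A read longer than the 3' adapter match position keeps only the insert
    upstream of the adapter.
    """
    params = params or CleaningParams()
    a5 = to_dna(adapter_5p)
    a3 = to_dna(adapter_3p)
    if not a5 or not a3:
        raise ValueError("both adapters must be non-empty")

    report = CleaningReport()
    survivors: list[str] = []
    for read in reads:
        seq = to_dna(read.sequence)
        report.raw_total += 1
        if _is_low_quality(read.quality, params):
            report.removed[RULE_NAMES[1]] += 1
            continue
        if _matches_prefix(seq, a5, params):
            report.removed[RULE_NAMES[2]] += 1
            continue
        pos = _find_adapter3(seq, a3, params)
        if pos is None:
            report.removed[RULE_NAMES[3]] += 1
            continue
        insert = seq[:pos]
        if not insert:
            report.removed[RULE_NAMES[4]] += 1
            continue
        if _is_polya(insert, params):
            report.removed[RULE_NAMES[5]] += 1
            continue
        if not (params.min_len <= len(insert) <= params.max_len):
            report.removed[RULE_NAMES[6]] += 1
            continue
        survivors.append(insert)
        report.clean_total += 1
        report.length_histogram[len(insert)] += 1

    report.check_partition()
    return survivors, report


def collapse_unique(
    inserts_control: Sequence[str], inserts_treatment: Sequence[str]
) -> list[CleanTag]:
    """Collapse clean inserts from both libraries into unique tags.

    Counts are conserved: sums of per-tag counts equal the clean totals.
    Tags are ordered by total count descending, then sequence.
    """
    counts: dict[str, list[int]] = {}
    for seq in inserts_control:
        counts.setdefault(seq, [0, 0])[0] += 1
    for seq in inserts_treatment:
        counts.setdefault(seq, [0, 0])[1] += 1
    tags = [CleanTag(seq, c, t) for seq, (c, t) in counts.items()]
    tags.sort(key=lambda tag: (-tag.total, tag.sequence))
    return tags


def length_distribution(tags: Sequence[CleanTag]) -> dict[int, int]:
    """Read-count-weighted length histogram over the 18-30 nt window."""
    hist = {n: 0 for n in range(MIN_TAG_LEN, MAX_TAG_LEN + 1)}
    for tag in tags:
        hist[len(tag.sequence)] += tag.total
    return hist
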