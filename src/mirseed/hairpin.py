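"""Novel miRNA prediction from unannotated genome-mapped tags.

For every unannotated tag locus, candidate precursor windows are excised
(the tag on either arm, the opposite arm allowed up to ``max_space`` nt
away, plus a short flank), folded with a thermodynamic engine
(ViennaRNA), trimmed to the hairpin extent, and evaluated against the
standard plant-miRNA candidate criteria:

  1. the window folds into a stem-loop hairpin;
  2. the mature sequence sits on one arm;
  3. fewer than 6 mismatches against the miRNA* partner;
  4. no loop or break in the miRNA* sequence;
  5. negative MFE (<= -18 kcal/mol), high MFEI, 30-70% A+U content;
  6. (optional) at most 4 substitutions versus a supplied set of known
     plant mature miRNAs — a conservation filter, off by default;

together with the duplex thresholds used by Mireap-style predictors:
>= 16 base pairs in the miRNA/miRNA* duplex, bulges <= 4 nt, duplex
asymmetry <= 4 nt, <= 300 nt between miRNA and miRNA*, 20 nt precursor
flank, mature length 18-25 nt and star length 20-23 nt, and at most 20
genomic copies of the tag.

MFEI is the minimum free energy index,
(|MFE| / precursor length * 100) / GC%, the standard normalization that
separates genuine pre-miRNAs from other RNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import RNA

from ._seq import au_fraction, gc_fraction, revcomp, to_dna, to_rna
from .annotation import GenomeHit

__all__ = [
    "FoldResult",
    "DuplexMetrics",
    "HairpinCandidate",
    "NovelMirnaParams",
    "fold",
    "pair_table",
    "measure_duplex",
    "compute_mfei",
    "apply_criteria",
    "excise_windows",
    "evaluate_window",
    "predict_novel",
]


@dataclass(frozen=True)
class FoldResult:
    sequence: str  # RNA alphabet
    structure: str  # dot-bracket
    mfe: float  # kcal/mol

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure/sequence length mismatch")


@dataclass(frozen=True)
class DuplexMetrics:
    n_base_pairs: int = 0
    n_mismatches: int = 0
    max_bulge: int = 0
    asymmetry: int = 0
    spacing: int = 0
    star_contains_loop: bool = False


@dataclass(frozen=True)
class NovelMirnaParams:
    """Prediction thresholds; defaults are the plant Mireap parameter set."""

    min_mature_len: int = 18
    max_mature_len: int = 25
    min_star_len: int = 20
    max_star_len: int = 23
    max_copies: int = 20
    max_mfe: float = -18.0  # kcal/mol
    max_space: int = 300  # nt between miRNA and miRNA*
    min_pairs: int = 16
    max_bulge: int = 4
    max_asymmetry: int = 4
    flank: int = 20
    max_mismatches: int = 5  # "less than 6 mismatches"
    min_mfei: float = 0.85
    au_range: tuple[float, float] = (0.30, 0.70)
    homology_ref: tuple[str, ...] = ()  # known matures for the optional filter
    max_substitutions: int = 4


@dataclass(frozen=True)
class HairpinCandidate:
    chrom: str
    start: int  # precursor interval, genome coordinates
    end: int
    strand: str
    precursor: str  # DNA, genome forward converted to mature strand
    mature: str
    mature_offset: int  # within precursor
    star: str
    fold: FoldResult
    duplex: DuplexMetrics
    mfei: float
    au_content: float
    criteria: dict[str, bool] = field(default_factory=dict)
    accepted: bool = False
    truncated: bool = False
    count_control: int = 0
    count_treatment: int = 0


def fold(sequence: str) -> FoldResult:
    """Minimum-free-energy secondary structure of an RNA sequence.

    Deterministic: identical input yields an identical structure and MFE.
    """
    rna = to_rna(sequence)
    if len(rna) < 40:
        raise ValueError("sequence shorter than 40 nt")
    if set(rna) - set("ACGU"):
        raise ValueError(f"non-ACGU characters: {sorted(set(rna) - set('ACGU'))}")
    structure, mfe = RNA.fold(rna)
    return FoldResult(rna, structure, float(mfe))


def pair_table(structure: str) -> list[int]:
    """0-based partner index per position, -1 for unpaired."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pt


def _unpaired_runs(flags: Sequence[bool]) -> int:
    """Longest run of True values."""
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def measure_duplex(
    fold_result: FoldResult, mature_offset: int, mature_len: int
) -> tuple[DuplexMetrics, str]:
    """Duplex metrics for the mature at ``mature_offset`` and its star.

    The star is the pairing-partner span of the mature arm (the duplex
    partner Dicer would release with 2-nt 3' overhangs).  Mismatches are
    mature positions left unpaired inside the duplex; bulges are the
    longest unpaired run on either strand; asymmetry is the difference of
    unpaired totals between the two strands; spacing is the distance
    between the mature and star intervals.  A mature straddling the
    terminal loop (partners on both sides, or pairing within itself) sets
    ``star_contains_loop``.
    """
    pt = pair_table(fold_result.structure)
    a, b = mature_offset, mature_offset + mature_len
    if a < 0 or b > len(pt):
        raise ValueError("mature lies outside the folded sequence")
    partners = [pt[i] for i in range(a, b) if pt[i] >= 0]
    if not partners:
        return DuplexMetrics(), ""

    self_paired = any(a <= p < b for p in partners)
    left = [p for p in partners if p < a]
    right = [p for p in partners if p >= b]
    crosses_loop = bool(left) and bool(right)
    if self_paired or crosses_loop:
        return DuplexMetrics(star_contains_loop=True), ""

    span = right if right else left
    s_lo, s_hi = min(span), max(span) + 1
    star = fold_result.sequence[s_lo:s_hi].replace("U", "T")

    # mismatches: unpaired mature positions; star-side unpaired positions
    # within the partner span count toward bulge/asymmetry.
    mature_unpaired = [pt[i] < 0 for i in range(a, b)]
    star_unpaired = [pt[i] < 0 for i in range(s_lo, s_hi)]
    n_pairs = mature_len - sum(mature_unpaired)
    spacing = (s_lo - b) if right else (a - s_hi)
    metrics = DuplexMetrics(
        n_base_pairs=n_pairs,
        n_mismatches=sum(mature_unpaired),
        max_bulge=max(_unpaired_runs(mature_unpaired), _unpaired_runs(star_unpaired)),
        asymmetry=abs(sum(mature_unpaired) - sum(star_unpaired)),
        spacing=max(spacing, 0),
        star_contains_loop=False,
    )
    return metrics, star


def compute_mfei(sequence: str, mfe: float) -> float:
    """Minimum free energy index: (|MFE| / length * 100) / GC%.

    Positive for negative MFE; raises for GC = 0 (undefined).
    """
    gc = gc_fraction(sequence)
    if gc == 0:
        raise ValueError("MFEI undefined for GC = 0")
    return (abs(min(mfe, 0.0)) / len(sequence) * 100.0) / (gc * 100.0)


def _substitutions(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(1 for x, y in zip(a, b) if x != y)


def apply_criteria(
    candidate: HairpinCandidate, params: NovelMirnaParams | None = None
) -> HairpinCandidate:
    """Evaluate all candidate criteria; never silent — each flag is recorded.

    Returns a copy with ``criteria`` filled and ``accepted`` set iff every
    flag is true.
    """
    params = params or NovelMirnaParams()
    d = candidate.duplex
    star_ok = bool(candidate.star) and not d.star_contains_loop
    flags = {
        "hairpin_formed": d.n_base_pairs > 0 and star_ok,
        "mature_on_arm": star_ok,
        "mismatches": d.n_mismatches <= params.max_mismatches,
        "star_intact": star_ok
        and _unpaired_runs(
            [c == "." for c in _star_structure(candidate)]
        ) <= params.max_bulge,
        "mfe": candidate.fold.mfe <= params.max_mfe,
        "mfei": candidate.mfei >= params.min_mfei,
        "au_content": params.au_range[0] <= candidate.au_content <= params.au_range[1],
        "min_pairs": d.n_base_pairs >= params.min_pairs,
        "max_bulge": d.max_bulge <= params.max_bulge,
        "asymmetry": d.asymmetry <= params.max_asymmetry,
        "spacing": d.spacing <= params.max_space,
        "mature_length": params.min_mature_len <= len(candidate.mature) <= params.max_mature_len,
        "star_length": params.min_star_len <= len(candidate.star) <= params.max_star_len,
    }
    if params.homology_ref:
        flags["homology"] = any(
            _substitutions(to_dna(candidate.mature), to_dna(ref)) <= params.max_substitutions
            for ref in params.homology_ref
        )
    return replace(candidate, criteria=flags, accepted=all(flags.values()))


def _star_structure(candidate: HairpinCandidate) -> str:
    if not candidate.star:
        return ""
    idx = candidate.fold.sequence.replace("U", "T").find(candidate.star)
    if idx < 0:
        return ""
    return candidate.fold.structure[idx : idx + len(candidate.star)]


def excise_windows(
    chrom_seq: str,
    hit: GenomeHit,
    params: NovelMirnaParams | None = None,
    extensions: Sequence[int] = (55, 80, 120, 180, 345),
) -> list[tuple[str, int, int, int, bool]]:
    """Candidate precursor windows around one genomic hit.

    For each orientation (star arm upstream or downstream of the mature)
    and each extension step up to max_space + star + flank, returns
    (window sequence on the mature strand, genome start, genome end,
    mature offset within the window, truncated-at-edge flag).
    """
    params = params or NovelMirnaParams()
    limit = params.max_space + params.flank
    exts = sorted({min(e, limit) for e in extensions})
    n = len(chrom_seq)
    windows = []
    for ext in exts:
        for left, right in ((params.flank, ext), (ext, params.flank)):
            ws = hit.start - left
            we = hit.end + right
            truncated = ws < 0 or we > n
            ws, we = max(ws, 0), min(we, n)
            seq = chrom_seq[ws:we]
            if hit.strand == "+":
                offset = hit.start - ws
            else:
                seq = revcomp(seq)
                offset = we - hit.end
            windows.append((seq, ws, we, offset, truncated))
    return windows


def evaluate_window(
    window_seq: str,
    mature_offset: int,
    mature_len: int,
    params: NovelMirnaParams | None = None,
    flank_trim: bool = True,
) -> HairpinCandidate | None:
    """Fold a window, trim to the hairpin extent, and evaluate criteria.

    The window is first folded whole; the precursor is then delimited as
    the outermost base pair enclosing the miRNA/miRNA* duplex plus the
    configured flank, refolded, and the criteria are applied to that
    precursor.  Returns None when the mature does not pair at all.
    """
    params = params or NovelMirnaParams()
    window_seq = to_dna(window_seq)
    if len(window_seq) < 40:
        return None
    fr = fold(window_seq)
    metrics, star = measure_duplex(fr, mature_offset, mature_len)
    if metrics.n_base_pairs == 0 and not metrics.star_contains_loop:
        return None

    # Trim to the hairpin extent (outermost pair enclosing the duplex, plus
    # flank) and refold, iterating to a fixed point: a wide window can fold
    # the flanking context into the stem, and re-delimiting after each
    # refold converges on the minimal self-contained precursor.
    trim_lo, trim_hi = 0, len(window_seq)
    for _ in range(4 if flank_trim else 0):
        if not star:
            break
        pt = pair_table(fr.structure)
        involved = [i for i in range(mature_offset, mature_offset + mature_len)]
        involved += [pt[i] for i in involved if pt[i] >= 0]
        lo, hi = min(involved), max(involved)
        out_lo, out_hi = lo, hi
        for i in range(lo, -1, -1):
            j = pt[i]
            if j >= hi:
                out_lo, out_hi = i, j
        new_lo = max(0, out_lo - params.flank)
        new_hi = min(len(window_seq), out_hi + 1 + params.flank)
        if new_hi - new_lo < 40 or (new_lo == 0 and new_hi == len(window_seq)):
            break
        window_seq = window_seq[new_lo:new_hi]
        mature_offset -= new_lo
        trim_lo += new_lo
        trim_hi = trim_lo + (new_hi - new_lo)
        fr = fold(window_seq)
        metrics, star = measure_duplex(fr, mature_offset, mature_len)

    mature = window_seq[mature_offset : mature_offset + mature_len]
    candidate = HairpinCandidate(
        chrom="",
        start=trim_lo,
        end=trim_hi,
        strand="+",
        precursor=window_seq,
        mature=mature,
        mature_offset=mature_offset,
        star=star,
        fold=fr,
        duplex=metrics,
        mfei=compute_mfei(window_seq, fr.mfe),
        au_content=au_fraction(window_seq),
    )
    return apply_criteria(candidate, params)


def predict_novel(
    genome: Mapping[str, str],
    unannotated_hits: Mapping[str, list[GenomeHit]],
    counts: Mapping[str, tuple[int, int]] | None = None,
    params: NovelMirnaParams | None = None,
) -> list[HairpinCandidate]:
    """End-to-end novel miRNA prediction over unannotated tag loci.

    ``unannotated_hits`` maps tag sequence -> genomic hits (from the
    annotation module); ``counts`` maps tag sequence -> (control,
    treatment) read counts.  Tags above the copy-number cap are skipped.
    Overlapping accepted precursors are deduplicated to the lowest-MFE
    candidate (ties: leftmost).  Deterministic for identical inputs.
    """
    params = params or NovelMirnaParams()
    counts = counts or {}
    accepted: list[HairpinCandidate] = []
    for tag_seq in sorted(unannotated_hits):
        hits = unannotated_hits[tag_seq]
        if not hits or hits[0].copy_number > params.max_copies:
            continue
        c_ctrl, c_trt = counts.get(tag_seq, (0, 0))
        for hit in hits:
            chrom_seq = to_dna(genome[hit.chrom])
            best: HairpinCandidate | None = None
            for seq, ws, we, offset, truncated in excise_windows(chrom_seq, hit, params):
                cand = evaluate_window(seq, offset, len(tag_seq), params)
                if cand is None or not cand.accepted:
                    continue
                if hit.strand == "+":
                    g_start, g_end = ws + cand.start, ws + cand.end
                else:
                    g_start, g_end = we - cand.end, we - cand.start
                cand = replace(
                    cand,
                    chrom=hit.chrom,
                    start=g_start,
                    end=g_end,
                    strand=hit.strand,
                    truncated=truncated,
                    count_control=c_ctrl,
                    count_treatment=c_trt,
                )
                if best is None or (cand.fold.mfe, cand.start) < (best.fold.mfe, best.start):
                    best = cand
            if best is not None:
                accepted.append(best)
    return _dedupe(accepted)


def _dedupe(candidates: list[HairpinCandidate]) -> list[HairpinCandidate]:
    """Keep the lowest-MFE candidate among overlapping accepted precursors."""
    chosen: list[HairpinCandidate] = []
    for cand in sorted(candidates, key=lambda c: (c.fold.mfe, c.chrom, c.start)):
        if any(
            c.chrom == cand.chrom and c.start < cand.end and cand.start < c.end
            for c in chosen
        ):
            continue
        chosen.append(cand)
    return sorted(chosen, key=lambda c: (c.chrom, c.start))
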