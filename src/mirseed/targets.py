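"""Plant miRNA target prediction by complementarity scoring.

Plant miRNAs pair near-perfectly with their targets, so putative sites
are found by penalty scoring of the antiparallel miRNA/mRNA duplex:
each mismatch costs 1, each G:U wobble 0.5 and each gap 2, with all
penalties doubled inside the seed region (miRNA positions 2-13 from the
5' end).  The total is the site's *expectation*; 0 is a perfect reverse
complement and sites above a cutoff (default 3.0) are discarded.  A site
whose only central defect is a mismatch at miRNA positions 9-11 — the
slicing site — is classified as acting by translational inhibition
rather than cleavage.

Target accessibility is measured as UPE, the ensemble energy needed to
unpair the site plus flanking bases (17 upstream, 13 downstream), via
the folding engine's constrained partition function; poorly accessible
sites (UPE >= 25 kcal/mol) are filtered when the engine is available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from ._seq import revcomp, to_dna

__all__ = [
    "TargetSite",
    "TargetParams",
    "score_site",
    "classify_mode",
    "scan_transcripts",
    "compute_upe",
]

_PAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U in RNA space
GAP = "-"


@dataclass(frozen=True)
class TargetParams:
    max_expectation: float = 3.0
    seed_start: int = 2  # 1-based miRNA positions with doubled penalties
    seed_end: int = 13
    mismatch_penalty: float = 1.0
    wobble_penalty: float = 0.5
    gap_penalty: float = 2.0
    max_gaps: int = 1
    central_start: int = 9  # central mismatch window for inhibition mode
    central_end: int = 11
    max_upe: float = 25.0  # kcal/mol
    upe_flank_up: int = 17
    upe_flank_down: int = 13
    upe_context: int = 150  # folding context either side of the opened region


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # site interval on the transcript, 0-based half-open
    end: int
    expectation: float
    alignment: str  # three-line text block, miRNA 5'->3' on top
    mode: str  # 'cleavage' | 'translational_inhibition'
    upe: float | None = None


def _position_penalty(kind: str, pos_1based: int, params: TargetParams) -> float:
    base = {
        "match": 0.0,
        "wobble": params.wobble_penalty,
        "mismatch": params.mismatch_penalty,
        "gap": params.gap_penalty,
    }[kind]
    if params.seed_start <= pos_1based <= params.seed_end:
        base *= 2.0
    return base


def _classify_pair(m: str, t: str) -> str:
    if (m, t) in _PAIR:
        return "match"
    if (m, t) in _WOBBLE:
        return "wobble"
    return "mismatch"  # ambiguous bases score as mismatches


def _score_columns(
    columns: list[tuple[str, str]], params: TargetParams
) -> tuple[float, list[str]]:
    """Score explicit alignment columns (miRNA base or GAP, target base or GAP).

    Returns (expectation, per-miRNA-position kinds).  ``kinds`` has one
    entry per miRNA base: 'match', 'wobble', 'mismatch' or 'gap' (the
    miRNA base bulged against a target gap).  A bulged target base
    contributes its gap penalty at the following miRNA position but no
    kinds entry.
    """
    total = 0.0
    kinds: list[str] = []
    pos = 0  # 1-based miRNA position of the last consumed miRNA base
    for m, t in columns:
        if m == GAP:  # bulged target base
            total += _position_penalty("gap", min(pos + 1, _mirna_len(columns)), params)
            continue
        pos += 1
        kind = "gap" if t == GAP else _classify_pair(m, t)
        kinds.append(kind)
        total += _position_penalty(kind, pos, params)
    return total, kinds


def _mirna_len(columns: list[tuple[str, str]]) -> int:
    return sum(1 for m, _ in columns if m != GAP)


def score_site(
    mirna: str, site: str, params: TargetParams | None = None
) -> tuple[float, str, list[str]]:
    """Expectation score and alignment of a miRNA against a candidate site.

    ``site`` is the target subsequence 5'->3'; the miRNA pairs with it
    antiparallel, so the miRNA is compared to the reverse complement of
    the site.  Site length may differ from the miRNA length by at most
    ``max_gaps``; the best single-gap placement is chosen.  Returns
    (expectation, alignment text, per-miRNA-position pairing kinds with
    'gap' marking a miRNA base bulged against the target).
    """
    params = params or TargetParams()
    mirna = to_dna(mirna)
    site = to_dna(site)
    # antiparallel duplex: miRNA position i+1 (from the 5' end) pairs with
    # the site read 3'->5', i.e. the reversed site at index i
    rc = site[::-1]
    dlen = len(site) - len(mirna)
    if abs(dlen) > params.max_gaps:
        raise ValueError("site/miRNA length difference exceeds the gap allowance")

    def columns_for(gap_at: int | None) -> list[tuple[str, str]]:
        if dlen == 0:
            return list(zip(mirna, rc))
        if dlen == 1:  # bulged target base at rc index gap_at
            cols = [(m, t) for m, t in zip(mirna[:gap_at], rc[:gap_at])]
            cols.append((GAP, rc[gap_at]))
            cols += list(zip(mirna[gap_at:], rc[gap_at + 1 :]))
            return cols
        # dlen == -1: miRNA base gap_at bulged against a target gap
        cols = [(m, t) for m, t in zip(mirna[:gap_at], rc[:gap_at])]
        cols.append((mirna[gap_at], GAP))
        cols += list(zip(mirna[gap_at + 1 :], rc[gap_at:]))
        return cols

    if dlen == 0:
        candidates = [columns_for(None)]
    elif dlen == 1:
        candidates = [columns_for(g) for g in range(len(rc))]
    else:
        candidates = [columns_for(g) for g in range(len(mirna))]

    best_total, best_kinds, best_cols = None, None, None
    for cols in candidates:
        total, kinds = _score_columns(cols, params)
        if best_total is None or total < best_total:
            best_total, best_kinds, best_cols = total, kinds, cols

    m_line = "".join(m for m, _ in best_cols)
    t_line = "".join(t for _, t in best_cols)
    marks = "".join(
        "|" if GAP not in (m, t) and (m, t) in _PAIR
        else ("o" if (m, t) in _WOBBLE else " ")
        for m, t in best_cols
    )
    alignment = f"miRNA  5' {m_line} 3'\n          {marks}\ntarget 3' {t_line} 5'"
    return best_total, alignment, best_kinds


def classify_mode(kinds: Sequence[str], params: TargetParams | None = None) -> str:
    """Cleavage vs translational inhibition from the pairing profile.

    Translational inhibition iff a mismatch or gap falls in the central
    window (miRNA positions 9-11); G:U wobbles do not count.
    """
    params = params or TargetParams()
    for i, kind in enumerate(kinds, start=1):
        if params.central_start <= i <= params.central_end and kind in ("mismatch", "gap"):
            return "translational_inhibition"
    return "cleavage"


def scan_transcripts(
    mirna_id: str,
    mirna: str,
    transcripts: Mapping[str, str],
    params: TargetParams | None = None,
    compute_accessibility: bool = True,
) -> list[TargetSite]:
    """All acceptable target sites of one miRNA across a transcriptome.

    Every window within one gap of the miRNA length is scored; sites with
    expectation <= the cutoff are kept, overlapping candidates are
    deduplicated to the best-scoring site (ties: smaller interval, then
    leftmost), and — when the folding engine is available and
    ``compute_accessibility`` is set — sites with UPE >= the cutoff are
    dropped.
    """
    params = params or TargetParams()
    if not transcripts:
        raise ValueError("empty transcriptome")
    mirna = to_dna(mirna)
    L = len(mirna)
    lengths = [L] + [L + d for d in range(1, params.max_gaps + 1)] + [
        L - d for d in range(1, params.max_gaps + 1)
    ]
    sites: list[TargetSite] = []
    for tx_id, tx_seq in transcripts.items():
        tx = to_dna(tx_seq)
        found: list[TargetSite] = []
        for wlen in lengths:
            for i in range(0, len(tx) - wlen + 1):
                window = tx[i : i + wlen]
                exp, aln, kinds = score_site(mirna, window, params)
                if exp <= params.max_expectation:
                    found.append(
                        TargetSite(
                            mirna_id, tx_id, i, i + wlen, exp, aln,
                            classify_mode(kinds, params),
                        )
                    )
        sites.extend(_dedupe_sites(found))

    if compute_accessibility:
        kept = []
        for site in sites:
            upe = compute_upe(
                transcripts[site.transcript_id], (site.start, site.end), params
            )
            if upe is None or upe < params.max_upe:
                kept.append(replace(site, upe=upe))
        sites = kept
    return sorted(sites, key=lambda s: (s.transcript_id, s.start, s.expectation))


def _dedupe_sites(found: list[TargetSite]) -> list[TargetSite]:
    chosen: list[TargetSite] = []
    for site in sorted(found, key=lambda s: (s.expectation, s.end - s.start, s.start)):
        if any(s.start < site.end and site.start < s.end for s in chosen):
            continue
        chosen.append(site)
    return chosen


def compute_upe(
    transcript: str,
    site_interval: tuple[int, int],
    params: TargetParams | None = None,
) -> float | None:
    """Energy (kcal/mol) to unpair a target site in its transcript context.

    The opened region is the site extended by the configured flanks
    (17 nt upstream, 13 nt downstream); the fold context is the region
    plus ``upe_context`` nt on each side.  UPE is the difference between
    the constrained (site forced single-stranded) and unconstrained
    ensemble free energies.  Returns None when the folding engine is
    unavailable.
    """
    params = params or TargetParams()
    try:
        import RNA
    except ImportError:  # pragma: no cover - engine present in supported envs
        import warnings

        warnings.warn("folding engine unavailable; UPE not computed")
        return None
    tx = to_dna(transcript)
    start, end = site_interval
    open_lo = max(0, start - params.upe_flank_up)
    open_hi = min(len(tx), end + params.upe_flank_down)
    ctx_lo = max(0, open_lo - params.upe_context)
    ctx_hi = min(len(tx), open_hi + params.upe_context)
    context = tx[ctx_lo:ctx_hi].replace("T", "U")

    fc_free = RNA.fold_compound(context)
    _, g_free = fc_free.pf()
    fc_open = RNA.fold_compound(context)
    for pos in range(open_lo - ctx_lo + 1, open_hi - ctx_lo + 1):  # 1-based
        fc_open.hc_add_up(pos)
    _, g_open = fc_open.pf()
    return float(g_open - g_free)
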