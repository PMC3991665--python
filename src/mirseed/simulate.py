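"""Ground-truth simulator for two-condition small-RNA sequencing.

Builds a random genome with planted loci — pre-miRNA hairpins (a known
and a novel subset), rRNA/tRNA/snoRNA/snRNA decoys, exon/intron gene
fragments and unstructured decoy loci — then samples paired
control/treatment read libraries with adapter-flanked inserts, planted
between-library fold changes, and contaminant reads matching each read
cleaning rule.  Every planted fact is recorded in a machine-readable
truth table so each pipeline stage can be tested for recovery.

The emulated design mirrors a drought study: two libraries (control vs
osmotic/PEG treatment), inserts dominated by 21-24 nt tags (21 nt the
modal class), the study's 5'/3' adapter sequences, and single-library
(no replicate) depths.

Planted hairpins are constructed by design — mature + engineered
miRNA* + loop — and verified against the novel-miRNA criteria at
construction, so the generator/evaluator round trip is exact; this is
bounded-time, unlike rejection sampling of random sequence.
Coordinates are 0-based, half-open; strands '+'/'-'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp, to_dna
from .annotation import GeneFeature
from .cleaning import CleaningParams, FastqRead, _find_adapter3, _is_polya, _matches_prefix
from .hairpin import NovelMirnaParams, evaluate_window

__all__ = [
    "SimulationConfig",
    "SimulationOutput",
    "SlotSizingError",
    "HairpinConstructionError",
    "generate_genome",
    "plant_hairpin",
    "simulate_libraries",
    "simulate_experiment",
]

# Adapter sequences of the emulated library protocol (RNA in the protocol,
# DNA on the sequencer).
ADAPTER_5P = "GUUCAGAGUUCUACAGUCCGACGAUC"
ADAPTER_3P = "UCGUAUGCCGUCUUCUGCUUGU"

CONTAMINANT_CLASSES = (
    "low_quality",
    "adapter5_contaminant",
    "no_adapter3",
    "no_insert",
    "polyA",
    "length_window",
)

#: Insert length distribution for planted tags: 21 nt dominates, then 24
#: and 22 — the canonical plant small-RNA profile.
TAG_LENGTH_PROBS = {20: 0.03, 21: 0.70, 22: 0.10, 23: 0.02, 24: 0.15}

#: Planted miRNA matures stay within 20-23 nt so their duplex star (the
#: same length for a designed perfect stem) satisfies the 20-23 nt
#: star-length bound of the prediction criteria.
MIRNA_LENGTH_PROBS = {20: 0.05, 21: 0.80, 22: 0.10, 23: 0.05}


class SlotSizingError(ValueError):
    """Planted loci do not fit in the requested genome."""


class HairpinConstructionError(RuntimeError):
    """A criteria-compliant hairpin could not be built for a mature."""


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 100_000
    gc_fraction: float = 0.5
    n_planted_mirnas: int = 20
    fraction_known: float = 0.5  # planted miRNAs entered into the known reference
    n_decoy_loci: int = 4  # per class: rRNA, tRNA, snoRNA, snRNA, exon, intron, decoy
    read_depth: int = 50_000  # reads per library
    read_length: int = 50
    adapter_5p: str = ADAPTER_5P
    adapter_3p: str = ADAPTER_3P
    de_spec: dict[str, float] = field(default_factory=dict)  # mirna id -> fold (trt/ctl)
    contaminant_fractions: dict[str, float] = field(
        default_factory=lambda: {name: 0.02 for name in CONTAMINANT_CLASSES}
    )
    substitution_rate: float = 0.0  # uniform sequencing-error rate on inserts
    clean_quality: int = 40  # Phred of clean reads
    low_quality: int = 2  # Phred profile of the low-quality contaminant class
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10 kb")
        if not (0.0 < self.gc_fraction < 1.0):
            raise ValueError("gc_fraction must lie in (0, 1)")
        fracs = self.contaminant_fractions
        unknown = set(fracs) - set(CONTAMINANT_CLASSES)
        if unknown:
            raise ValueError(f"unknown contaminant classes: {sorted(unknown)}")
        if any(not (0.0 <= f <= 1.0) for f in fracs.values()):
            raise ValueError("contaminant fractions must lie in [0, 1]")
        if sum(fracs.values()) >= 1.0:
            raise ValueError("contaminant fractions must sum to < 1")
        for mid in self.de_spec:
            if not self._is_mirna_id(mid):
                raise ValueError(f"de_spec id {mid!r} is not a planted miRNA id")
        if any(f <= 0 for f in self.de_spec.values()):
            raise ValueError("fold changes must be positive")

    def _is_mirna_id(self, mid: str) -> bool:
        if not mid.startswith("mir-"):
            return False
        try:
            return 0 <= int(mid.split("-")[1]) < self.n_planted_mirnas
        except (IndexError, ValueError):
            return False


@dataclass
class SimulationOutput:
    config: SimulationConfig
    genome: dict[str, str]
    truth: pd.DataFrame  # one row per planted locus
    reads_control: list[FastqRead]
    reads_treatment: list[FastqRead]
    read_labels: dict[str, pd.DataFrame]  # per library: read_id, label
    contaminant_counts: dict[str, dict[str, int]]  # per library, per class
    mature_ref: dict[str, str]  # known-miRNA reference (planted known subset)
    ncrna_refs: dict[str, dict[str, str]]  # 'genbank'/'rfam' reference pools
    gene_features: list[GeneFeature]


TRUTH_COLUMNS = [
    "locus_id", "locus_class", "chrom", "start", "end", "strand",
    "tag_seq", "tag_start", "tag_end", "count_control", "count_treatment",
    "true_fold",
]

# class -> planted locus length
_LOCUS_LEN = {
    "rRNA": 120, "tRNA": 80, "snoRNA": 100, "snRNA": 110,
    "exon": 200, "intron": 200, "decoy": 60,
}
_CHROM = "chr1"


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _tag_length(rng: np.random.Generator, probs: dict[int, float] = TAG_LENGTH_PROBS) -> int:
    lens = sorted(probs)
    return int(rng.choice(lens, p=[probs[n] for n in lens]))


def _tag_is_clean(tag: str, config: SimulationConfig, cp: CleaningParams) -> bool:
    """Would a read built from this insert survive the cleaning cascade?"""
    a5, a3 = to_dna(config.adapter_5p), to_dna(config.adapter_3p)
    read = tag + a3
    return (
        not _matches_prefix(read, a5, cp)
        and _find_adapter3(read, a3, cp) == len(tag)
        and not _is_polya(tag, cp)
    )


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome at the requested GC with reserved, non-overlapping slots.

    Returns the genome and a truth-table skeleton (loci positioned and
    classed, tags and counts not yet assigned).  Deterministic for a given
    config.  Raises :class:`SlotSizingError` when the planted loci cannot
    fit with margins.
    """
    rng = np.random.default_rng(config.seed)
    seq = _random_seq(rng, config.genome_length, config.gc_fraction)

    slots: list[tuple[str, int]] = []  # (class, slot length incl. margin)
    hairpin_slot = 2 * 25 + 8 + 2 * 30  # mature + star + loop + margins
    for i in range(config.n_planted_mirnas):
        slots.append(("miRNA", hairpin_slot))
    for cls, length in _LOCUS_LEN.items():
        for _ in range(config.n_decoy_loci):
            slots.append((cls, length + 20))

    margin = 60  # spacing so windows around neighbouring loci never overlap
    demand = sum(n + margin for _, n in slots) + 2 * margin
    if demand > config.genome_length:
        raise SlotSizingError(
            f"{len(slots)} loci need {demand} nt but the genome is {config.genome_length} nt"
        )

    order = rng.permutation(len(slots))
    # spread slots evenly with random jitter inside each bin
    rows = []
    n_slots = len(slots)
    bin_size = config.genome_length // max(n_slots, 1)
    counters: dict[str, int] = {}
    for bin_idx, slot_idx in enumerate(order):
        cls, length = slots[slot_idx]
        lo = bin_idx * bin_size + margin // 2
        hi = (bin_idx + 1) * bin_size - length - margin // 2
        if hi <= lo:
            raise SlotSizingError("loci too dense for the requested genome length")
        start = int(rng.integers(lo, hi))
        k = counters.get(cls, 0)
        counters[cls] = k + 1
        prefix = "mir" if cls == "miRNA" else cls.lower()
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append(
            {
                "locus_id": f"{prefix}-{k}",
                "locus_class": cls,
                "chrom": _CHROM,
                "start": start,
                "end": start + length,
                "strand": strand,
                "tag_seq": "",
                "tag_start": -1,
                "tag_end": -1,
                "count_control": 0,
                "count_treatment": 0,
                "true_fold": 1.0,
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS).sort_values("start").reset_index(drop=True)
    return {_CHROM: seq}, truth


_LOOP_POOL = ("TTCGAATT", "TCTCGAGA", "GTTCAAAC", "TAACGTTA", "CTTTGAAG")


def plant_hairpin(
    chrom_seq: str,
    mature: str,
    start: int,
    strand: str,
    rng: np.random.Generator,
    params: NovelMirnaParams | None = None,
    max_tries: int = 40,
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Insert a criteria-compliant precursor at ``start``; return new
    chromosome sequence, the precursor interval and the mature interval.

    The precursor is mature + loop + reverse-complement star; candidate
    loops are tried (with re-randomized star context) until the planted
    window, evaluated exactly as the predictor evaluates it, passes all
    criteria.  Raises :class:`HairpinConstructionError` with the failing
    flags after ``max_tries``.
    """
    params = params or NovelMirnaParams()
    mature = to_dna(mature)
    if not (18 <= len(mature) <= 25):
        raise ValueError("mature length must lie in [18, 25]")
    last_flags: dict[str, bool] = {}
    for attempt in range(max_tries):
        loop = _LOOP_POOL[attempt % len(_LOOP_POOL)]
        hairpin = mature + loop + revcomp(mature)
        if strand == "-":
            insert = revcomp(hairpin)
            mat_lo = start + len(hairpin) - len(mature)
        else:
            insert = hairpin
            mat_lo = start
        new_seq = chrom_seq[:start] + insert + chrom_seq[start + len(insert):]
        # evaluate the planted window exactly as the predictor would
        w_lo = max(0, start - params.flank)
        w_hi = min(len(new_seq), start + len(insert) + params.flank)
        window = new_seq[w_lo:w_hi]
        if strand == "-":
            window = revcomp(window)
            offset = w_hi - (mat_lo + len(mature))
        else:
            offset = mat_lo - w_lo
        cand = evaluate_window(window, offset, len(mature), params)
        if cand is not None and cand.accepted:
            return new_seq, (start, start + len(insert)), (mat_lo, mat_lo + len(mature))
        last_flags = dict(cand.criteria) if cand is not None else {}
        # perturb the context: re-randomize the two flank stretches
        gc = 0.5
        left = _random_seq(rng, params.flank, gc)
        right = _random_seq(rng, params.flank, gc)
        chrom_seq = (
            chrom_seq[: max(0, start - params.flank)]
            + left
            + chrom_seq[start : start + len(insert)]
            + right
            + chrom_seq[start + len(insert) + params.flank :]
        )
    failing = sorted(k for k, v in last_flags.items() if not v) or ["no fold"]
    raise HairpinConstructionError(
        f"no compliant hairpin for mature {mature} after {max_tries} tries; "
        f"failing criteria: {failing}"
    )


def _random_mature(rng: np.random.Generator, config: SimulationConfig, cp: CleaningParams) -> str:
    for _ in range(200):
        mature = _random_seq(rng, _tag_length(rng, MIRNA_LENGTH_PROBS), 0.5)
        if _tag_is_clean(mature, config, cp):
            return mature
    raise RuntimeError("could not draw a clean mature sequence")


def _plant_all(
    config: SimulationConfig, genome: dict[str, str], truth: pd.DataFrame
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write locus sequences into the genome and record tags in the truth."""
    rng = np.random.default_rng(config.seed + 1)
    cp = CleaningParams()
    seq = genome[_CHROM]
    truth = truth.copy()
    for idx in truth.index:
        row = truth.loc[idx]
        cls, start, strand = row.locus_class, int(row.start), row.strand
        if cls == "miRNA":
            mature = _random_mature(rng, config, cp)
            seq, (lo, hi), (m_lo, m_hi) = plant_hairpin(seq, mature, start, strand, rng)
            truth.loc[idx, ["tag_seq", "tag_start", "tag_end", "end"]] = [
                mature, m_lo, m_hi, hi,
            ]
        else:
            length = int(row.end - row.start)
            for _ in range(200):
                locus = _random_seq(rng, length, config.gc_fraction)
                t_off = int(rng.integers(5, length - 30))
                tag_fwd = locus[t_off : t_off + _tag_length(rng)]
                if _tag_is_clean(tag_fwd, config, cp):
                    break
            else:  # pragma: no cover - overwhelmingly unlikely
                raise RuntimeError("could not draw a clean locus tag")
            seq = seq[:start] + locus + seq[start + length :]
            # the sequenced tag is read off the locus strand
            tag = tag_fwd if strand == "+" else revcomp(tag_fwd)
            truth.loc[idx, ["tag_seq", "tag_start", "tag_end"]] = [
                tag, start + t_off, start + t_off + len(tag_fwd),
            ]
    return {_CHROM: seq}, truth


def _phred_string(q: int, n: int) -> str:
    return chr(q + 33) * n


def _make_clean_read(
    insert: str, config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, str]:
    a3 = to_dna(config.adapter_3p)
    read = (insert + a3)[: config.read_length]
    if len(read) < config.read_length:
        read += _random_seq(rng, config.read_length - len(read), config.gc_fraction)
    if config.substitution_rate > 0:
        bases = list(read)
        for i in range(len(insert)):
            if rng.random() < config.substitution_rate:
                bases[i] = rng.choice([b for b in "ACGT" if b != bases[i]])
        read = "".join(bases)
    return read, _phred_string(config.clean_quality, len(read))


def _make_contaminant(
    cls: str, config: SimulationConfig, rng: np.random.Generator, cp: CleaningParams
) -> tuple[str, str]:
    a5, a3 = to_dna(config.adapter_5p), to_dna(config.adapter_3p)
    L = config.read_length
    q_hi = _phred_string(config.clean_quality, L)
    if cls == "low_quality":
        seq, _ = _make_clean_read(_random_seq(rng, 21, 0.5), config, rng)
        return seq, _phred_string(config.low_quality, L)
    if cls == "adapter5_contaminant":
        seq = (a5 + _random_seq(rng, 21, 0.5) + a3)[:L]
        seq += _random_seq(rng, L - len(seq), config.gc_fraction)
        return seq, q_hi
    if cls == "no_adapter3":
        while True:
            seq = _random_seq(rng, L, config.gc_fraction)
            if _find_adapter3(seq, a3, cp) is None and not _matches_prefix(seq, a5, cp):
                return seq, q_hi
    if cls == "no_insert":
        seq = a3[:L]
        seq += _random_seq(rng, L - len(seq), config.gc_fraction)
        # adapter dimer: ensure no accidental 5' adapter call
        return seq, q_hi
    if cls == "polyA":
        n = int(rng.integers(18, 26))
        seq = ("A" * n + a3)[:L]
        seq += _random_seq(rng, L - len(seq), config.gc_fraction)
        return seq, q_hi
    if cls == "length_window":
        insert = _random_seq(rng, int(rng.integers(10, 18)), 0.5)
        while not _tag_is_clean(insert, config, cp):
            insert = _random_seq(rng, int(rng.integers(10, 18)), 0.5)
        seq = (insert + a3)[:L]
        seq += _random_seq(rng, L - len(seq), config.gc_fraction)
        return seq, q_hi
    raise ValueError(f"unknown contaminant class {cls!r}")


def simulate_libraries(
    config: SimulationConfig, genome: dict[str, str], truth: pd.DataFrame
) -> tuple[list[FastqRead], list[FastqRead], pd.DataFrame, dict[str, pd.DataFrame], dict[str, dict[str, int]]]:
    """Sample the control and treatment FASTQ libraries.

    Expressing loci receive log-normal base abundances; treatment
    abundances are scaled by the planted fold changes.  Per-locus read
    counts are independent Poisson draws around those abundances, so a
    planted fold change is realized exactly in expectation (no
    compositional renormalization); ``read_depth`` is therefore the
    expected, not exact, library size.  Contaminant reads are injected
    per class at the configured fractions of ``read_depth``.  Returns
    (reads_control, reads_treatment, truth with realized counts,
    per-read labels per library, contaminant counts per library).
    """
    rng = np.random.default_rng(config.seed + 2)
    cp = CleaningParams()
    truth = truth.copy()

    expressing = truth[truth["tag_seq"] != ""].reset_index()
    n_loci = len(expressing)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_loci)
    folds = np.array(
        [config.de_spec.get(lid, 1.0) for lid in expressing["locus_id"]]
    )
    weights = {"control": base, "treatment": base * folds}

    reads: dict[str, list[FastqRead]] = {"control": [], "treatment": []}
    labels: dict[str, list[tuple[str, str]]] = {"control": [], "treatment": []}
    contam_counts: dict[str, dict[str, int]] = {}
    counts_col = {"control": "count_control", "treatment": "count_treatment"}

    for lib in ("control", "treatment"):
        n_contam = {
            cls: int(round(config.read_depth * frac))
            for cls, frac in config.contaminant_fractions.items()
        }
        contam_counts[lib] = dict(n_contam)
        n_clean = config.read_depth - sum(n_contam.values())
        lam = n_clean * weights[lib] / weights["control"].sum()
        locus_draws = rng.poisson(lam)
        serial = 0
        for locus_pos, n_reads in enumerate(locus_draws):
            info = expressing.iloc[locus_pos]
            truth.loc[info["index"], counts_col[lib]] += int(n_reads)
            for _ in range(n_reads):
                seq, qual = _make_clean_read(info.tag_seq, config, rng)
                rid = f"{lib}:{serial}:{info.locus_id}"
                reads[lib].append(FastqRead(rid, seq, qual))
                labels[lib].append((rid, info.locus_id))
                serial += 1
        for cls, n_reads in n_contam.items():
            for _ in range(n_reads):
                seq, qual = _make_contaminant(cls, config, rng, cp)
                rid = f"{lib}:{serial}:contaminant:{cls}"
                reads[lib].append(FastqRead(rid, seq, qual))
                labels[lib].append((rid, f"contaminant:{cls}"))
                serial += 1
        # fixed shuffle so library files do not come out grouped by locus
        order = rng.permutation(len(reads[lib]))
        reads[lib] = [reads[lib][i] for i in order]
        labels[lib] = [labels[lib][i] for i in order]

    label_frames = {
        lib: pd.DataFrame(labels[lib], columns=["read_id", "label"])
        for lib in ("control", "treatment")
    }
    return (
        reads["control"], reads["treatment"], truth, label_frames, contam_counts,
    )


def simulate_experiment(config: SimulationConfig) -> SimulationOutput:
    """Full simulation: genome, planted loci, libraries and references.

    The known-miRNA reference holds the first ``fraction_known`` share of
    planted miRNAs (these should be recovered as known); the rest are the
    novel-discovery truth.  ncRNA locus sequences are split into a
    'genbank' pool (rRNA, tRNA) and an 'rfam' pool (snoRNA, snRNA), and
    exon/intron loci become gene features, so the annotation module can
    run against the same references a real analysis would load.
    """
    genome, truth = generate_genome(config)
    genome, truth = _plant_all(config, genome, truth)
    ctrl, trt, truth, labels, contam = simulate_libraries(config, genome, truth)

    truth["true_fold"] = [
        config.de_spec.get(lid, 1.0) if cls == "miRNA" else 1.0
        for lid, cls in zip(truth["locus_id"], truth["locus_class"])
    ]
    mirnas = truth[truth["locus_class"] == "miRNA"]
    n_known = int(round(config.fraction_known * len(mirnas)))
    known_ids = list(mirnas["locus_id"][:n_known])
    truth["known"] = truth["locus_id"].isin(known_ids)
    mature_ref = {
        f"ref-{lid}": row_seq
        for lid, row_seq in zip(mirnas["locus_id"], mirnas["tag_seq"])
        if lid in known_ids
    }

    seq = genome[_CHROM]
    ncrna_refs: dict[str, dict[str, str]] = {"genbank": {}, "rfam": {}}
    pool_of = {"rRNA": "genbank", "tRNA": "genbank", "snoRNA": "rfam", "snRNA": "rfam"}
    gene_features: list[GeneFeature] = []
    for row in truth.itertuples():
        if row.locus_class in pool_of:
            ncrna_refs[pool_of[row.locus_class]][row.locus_id] = seq[row.start:row.end]
        elif row.locus_class in ("exon", "intron"):
            gene_features.append(
                GeneFeature(
                    row.chrom, int(row.start), int(row.end), row.strand,
                    row.locus_class.lower(), row.locus_id,
                )
            )
    return SimulationOutput(
        config=config,
        genome=genome,
        truth=truth,
        reads_control=ctrl,
        reads_treatment=trt,
        read_labels=labels,
        contaminant_counts=contam,
        mature_ref=mature_ref,
        ncrna_refs=ncrna_refs,
        gene_features=gene_features,
    )
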