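"""Count-based differential expression between two sequencing libraries.

One small-RNA library per condition (no replicates), so significance is
assessed with the Audic-Claverie exact statistic: conditional on observing
``x`` reads for a tag in a library of depth ``N1``, the count ``y`` in a
second library of depth ``N2`` follows

    p(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1))

which is a negative binomial with ``x+1`` successes and success
probability ``N1/(N1+N2)``.  Equivalently, conditional on the pair total
``x+y`` the treatment count is Binomial(x+y, N2/(N1+N2)); the two-sided
p-value uses that conditioning so that swapping the libraries leaves it
exactly unchanged.  Expression levels are normalized to tags per million
(TPM) and regulation is called at a 2-fold threshold on the
log2(treatment/control) ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, nbinom

__all__ = [
    "CountRow",
    "DEResult",
    "normalize_tpm",
    "fold_change",
    "count_probability",
    "count_p_value",
    "differential_expression",
    "select_differential",
]

#: TPM stand-in for a zero count, used only when forming expression ratios.
ZERO_TPM_PSEUDO = 0.01


@dataclass(frozen=True)
class CountRow:
    """Raw counts for one miRNA: ``x`` in control, ``y`` in treatment."""

    mirna_id: str
    x: int
    y: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"negative count for {self.mirna_id}")


@dataclass(frozen=True)
class DEResult:
    mirna_id: str
    tpm_control: float
    tpm_treatment: float
    log2fc: float
    p_value: float
    call: str  # 'up' | 'down' | 'unchanged'


def normalize_tpm(count: int, library_total: int) -> float:
    """Tags-per-million: count / library_total * 1e6.

    ``library_total`` is the library's clean-read total.
    """
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / library_total * 1_000_000.0


def fold_change(tpm_treatment: float, tpm_control: float) -> float:
    """log2(treatment/control); zero TPMs are replaced by a 0.01 pseudo-value.

    Both zero gives log2(pseudo/pseudo) = 0.
    """
    t = tpm_treatment if tpm_treatment > 0 else ZERO_TPM_PSEUDO
    c = tpm_control if tpm_control > 0 else ZERO_TPM_PSEUDO
    return math.log2(t / c)


def _nbinom_params(x: int, n1: float, n2: float) -> tuple[int, float]:
    # y | x ~ NB(x+1 successes, p = N1/(N1+N2))
    return x + 1, n1 / (n1 + n2)


def count_probability(y: int, x: int, n1: float, n2: float) -> float:
    """Audic-Claverie conditional probability p(y | x) for depths N1, N2."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library depths must be positive")
    n, p = _nbinom_params(x, n1, n2)
    return float(nbinom.pmf(y, n, p))


def count_p_value(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided exact p-value for observing counts (x, y) at depths (N1, N2).

    Conditional on the pair total n = x + y, the treatment count follows
    Binomial(n, N2/(N1+N2)) under the null of equal proportions — the
    same conditioning that makes the Audic-Claverie pmf above exact.  The
    two-sided p sums all outcomes y' in [0, n] whose probability does not
    exceed that of the observed y (the minimum-likelihood tail).  This
    conditioning makes the p-value exactly invariant under swapping the
    libraries, which the one-sided-conditional tail is not.

    The binomial pmf is unimodal, so the rejection set is the complement
    of a central interval; the far-side boundary is located by binary
    search on the log-pmf, keeping the computation stable for counts up
    to ~1e7.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library depths must be positive")
    n = x + y
    if n == 0:
        return 1.0
    q = n2 / (n1 + n2)
    dist = binom(n, q)
    lp_y = dist.logpmf(y)
    mode = int(math.floor((n + 1) * q))
    mode = min(max(mode, 0), n)
    # pmf can be flat across adjacent integers; compare with a tolerance so
    # ties (e.g. the symmetric x == y, N1 == N2 case) are included.
    tol = 1e-12

    if y == mode or dist.logpmf(mode) <= lp_y + tol:
        return 1.0

    if y > mode:
        right = float(dist.sf(y - 1))  # P(Y >= y)
        # largest y_l in [0, mode) with pmf(y_l) <= pmf(y): logpmf increasing there
        lo, hi = 0, mode - 1
        boundary = -1
        while lo <= hi:
            mid = (lo + hi) // 2
            if dist.logpmf(mid) <= lp_y + tol:
                boundary = mid
                lo = mid + 1
            else:
                hi = mid - 1
        left = float(dist.cdf(boundary)) if boundary >= 0 else 0.0
        return min(1.0, left + right)

    # y < mode
    left = float(dist.cdf(y))  # P(Y <= y)
    # smallest y_r in (mode, n] with pmf(y_r) <= pmf(y): logpmf decreasing there
    lo, hi = mode + 1, n
    boundary = n + 1
    while lo <= hi:
        mid = (lo + hi) // 2
        if dist.logpmf(mid) <= lp_y + tol:
            boundary = mid
            hi = mid - 1
        else:
            lo = mid + 1
    right = float(dist.sf(boundary - 1)) if boundary <= n else 0.0
    return min(1.0, left + right)


def _call(log2fc: float, threshold_log2: float) -> str:
    if log2fc >= threshold_log2:
        return "up"
    if log2fc <= -threshold_log2:
        return "down"
    return "unchanged"


def differential_expression(
    rows: Iterable[CountRow] | pd.DataFrame,
    total_control: int,
    total_treatment: int,
    fc_threshold: float = 2.0,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-miRNA TPMs, log2 fold change, exact p-value and regulation call.

    ``rows`` may be CountRow objects or a DataFrame with columns
    ``mirna_id``, ``x``, ``y``.  Rows with zero counts in both libraries are
    reported with TPM 0, log2fc 0 and p-value 1 (never as pseudo-count
    artifacts).  With ``bh_correction`` a Benjamini-Hochberg ``q_value``
    column is appended.
    """
    if isinstance(rows, pd.DataFrame):
        items = [CountRow(str(r.mirna_id), int(r.x), int(r.y)) for r in rows.itertuples()]
    else:
        items = list(rows)
    records = []
    for row in items:
        tpm_c = normalize_tpm(row.x, total_control)
        tpm_t = normalize_tpm(row.y, total_treatment)
        if row.x == 0 and row.y == 0:
            lfc, p = 0.0, 1.0
        else:
            lfc = fold_change(tpm_t, tpm_c)
            p = count_p_value(row.x, row.y, total_control, total_treatment)
        records.append(
            DEResult(row.mirna_id, tpm_c, tpm_t, lfc, p, _call(lfc, math.log2(fc_threshold)))
        )
    df = pd.DataFrame([r.__dict__ for r in records])
    if bh_correction and len(df):
        from statsmodels.stats.multitest import multipletests

        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def select_differential(
    de_table: pd.DataFrame, fc_threshold: float = 2.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a DE table into up/down lists at the fold threshold.

    Up: log2fc >= log2(threshold); down: log2fc <= -log2(threshold).
    Each list is sorted by |log2fc| descending, ties broken by id.
    """
    log2_thr = math.log2(fc_threshold)

    def _sorted(sub: pd.DataFrame) -> pd.DataFrame:
        sub = sub.assign(_abs=sub["log2fc"].abs())
        sub = sub.sort_values(["_abs", "mirna_id"], ascending=[False, True])
        return sub.drop(columns="_abs").reset_index(drop=True)

    up = _sorted(de_table[de_table["log2fc"] >= log2_thr])
    down = _sorted(de_table[de_table["log2fc"] <= -log2_thr])
    return up, down


def ratio_classes(de_table: pd.DataFrame) -> pd.Series:
    """Scatter-plot color classes by treatment/control TPM ratio.

    'high' for ratio > 2, 'mid' for 1/2 < ratio <= 2, 'low' for ratio <= 1/2
    (pseudo-values applied to zeros).
    """
    ratios = de_table.apply(
        lambda r: (r.tpm_treatment or ZERO_TPM_PSEUDO) / (r.tpm_control or ZERO_TPM_PSEUDO),
        axis=1,
    )
    return pd.cut(
        ratios, bins=[0, 0.5, 2.0, np.inf], labels=["low", "mid", "high"], right=True
    )
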