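"""Relative quantification of qPCR Ct tables by the 2^-ddCt method.

Ct values are normalized against an internal reference gene (ef1a in the
drought study this pipeline emulates): dCt = Ct(gene) - Ct(reference) per
condition and biological replicate (technical replicates averaged first),
ddCt = dCt(treatment) - dCt(control), and the relative fold change is
2^-ddCt, summarized as mean +/- SD across biological replicates.
Amplification efficiency is assumed to be 100%, the ddCt model's standard
assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RelativeExpression",
    "delta_ct",
    "ddct_fold_change",
    "relative_expression",
    "concordance_report",
]

CT_COLUMNS = ["target_id", "condition", "bio_rep", "tech_rep", "ct"]


@dataclass(frozen=True)
class RelativeExpression:
    target_id: str
    fold_change: float  # mean of per-replicate 2^-ddCt
    sd: float
    n_replicates: int

    @property
    def direction(self) -> str:
        return "up" if self.fold_change > 1 else ("down" if self.fold_change < 1 else "flat")


def _validate(ct_table: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return ct_table


def delta_ct(ct_table: pd.DataFrame, target_id: str, reference_id: str) -> pd.DataFrame:
    """dCt per (condition, biological replicate) for one assay.

    Technical replicates are averaged within each biological replicate
    before the subtraction.  Returns columns condition, bio_rep, dct.
    """
    ct_table = _validate(ct_table)
    means = (
        ct_table.groupby(["target_id", "condition", "bio_rep"])["ct"].mean().reset_index()
    )
    tgt = means[means["target_id"] == target_id]
    ref = means[means["target_id"] == reference_id]
    if tgt.empty:
        raise ValueError(f"no Ct rows for target {target_id!r}")
    merged = tgt.merge(ref, on=["condition", "bio_rep"], suffixes=("", "_ref"), how="left")
    if merged["ct_ref"].isna().any():
        bad = merged[merged["ct_ref"].isna()][["condition", "bio_rep"]].to_records(index=False)
        raise ValueError(
            f"missing reference {reference_id!r} Ct for (condition, replicate): {list(bad)}"
        )
    merged["dct"] = merged["ct"] - merged["ct_ref"]
    return merged[["condition", "bio_rep", "dct"]]


def ddct_fold_change(dct: pd.DataFrame) -> RelativeExpression | pd.Series:
    """Per-replicate ddCt = dCt(treatment) - dCt(control); fold = 2^-ddCt.

    Input is the output of :func:`delta_ct`; replicates are paired by
    ``bio_rep``.  Returns the mean +/- SD (ddof=1 when n > 1) of the
    per-replicate fold changes.
    """
    wide = dct.pivot(index="bio_rep", columns="condition", values="dct")
    if not {"control", "treatment"} <= set(wide.columns):
        raise ValueError("dCt table must contain both 'control' and 'treatment'")
    wide = wide.dropna()
    ddct = wide["treatment"] - wide["control"]
    folds = np.exp2(-ddct)
    sd = float(folds.std(ddof=1)) if len(folds) > 1 else 0.0
    return RelativeExpression("", float(folds.mean()), sd, len(folds))


def relative_expression(
    ct_table: pd.DataFrame, reference_id: str = "ef1a"
) -> pd.DataFrame:
    """2^-ddCt fold changes for every assay in a Ct table.

    Returns one row per non-reference target: fold_change (mean over
    biological replicates), sd, n_replicates, direction.
    """
    ct_table = _validate(ct_table)
    results = []
    for target in ct_table["target_id"].unique():
        if target == reference_id:
            continue
        rel = ddct_fold_change(delta_ct(ct_table, target, reference_id))
        results.append(
            {
                "target_id": target,
                "fold_change": rel.fold_change,
                "sd": rel.sd,
                "n_replicates": rel.n_replicates,
                "direction": RelativeExpression(target, rel.fold_change, rel.sd, rel.n_replicates).direction,
            }
        )
    return pd.DataFrame(results)


def concordance_report(
    mirna_qpcr: pd.DataFrame,
    target_qpcr: pd.DataFrame,
    sequencing_calls: pd.DataFrame,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Cross-method validation of candidate stress-responsive miRNAs.

    For each (miRNA, target gene) pair, flags whether (a) the qPCR
    direction of the miRNA matches its sequencing regulation call and
    (b) the miRNA and its target move in opposite directions by qPCR.
    miRNAs with both flags true are the validated candidates — in the
    drought study's terms, the "potential drought-responsive" set.

    Parameters
    ----------
    mirna_qpcr, target_qpcr : output of :func:`relative_expression`.
    sequencing_calls : columns mirna_id, call ('up'/'down'/'unchanged').
    pairs : columns mirna_id, target_id mapping each miRNA to its
        predicted target gene.
    """
    mirna_dir = mirna_qpcr.set_index("target_id")["direction"]
    gene_dir = target_qpcr.set_index("target_id")["direction"]
    seq_call = sequencing_calls.set_index("mirna_id")["call"]
    rows = []
    for pair in pairs.itertuples():
        m_dir = mirna_dir.get(pair.mirna_id)
        g_dir = gene_dir.get(pair.target_id)
        s_call = seq_call.get(pair.mirna_id)
        methods_agree = m_dir is not None and s_call in ("up", "down") and m_dir == s_call
        anticorrelated = (
            m_dir in ("up", "down") and g_dir in ("up", "down") and m_dir != g_dir
        )
        rows.append(
            {
                "mirna_id": pair.mirna_id,
                "target_id": pair.target_id,
                "qpcr_direction": m_dir,
                "sequencing_call": s_call,
                "target_direction": g_dir,
                "methods_agree": bool(methods_agree),
                "target_anticorrelated": bool(anticorrelated),
                "candidate": bool(methods_agree and anticorrelated),
            }
        )
    return pd.DataFrame(rows)
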