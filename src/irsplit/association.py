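"""Association data products: ranked selections, Z-score heatmap matrices,
volcano coordinates and quadrant summaries.

Heatmap columns follow the cohort's fixed block order — control samples
first, then the low-risk (mutated-IGHV-like) block, then the high-risk
(unmutated-IGHV-like) block — rather than any clustering. Rows are Z scores
of TPM per transcript (sample sd, n-1); constant rows map to all-zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ScreenResult, SetAssignment, _screen_frame
from .quantify import DEFAULT_EPSILON, IRTable


def select_top_n(
    sa: SetAssignment,
    log2_ratio: pd.Series,
    source_set: str = "set-I",
    n: int = 200,
) -> list[str]:
    """The top ``n`` transcripts of a set, ranked by ascending screen p-value.

    ``source_set`` is ``set-I``/``set-II`` or a subset like ``set-IA``.
    Ranking uses the p-value of that set's own directional intronic screen;
    ties break by larger \\|log2 ratio\\|, then lexicographic transcript id.
    Asking for more transcripts than the set holds returns them all.
    """
    base, subset = _parse_set_label(source_set)
    members = sa.members(base, subset)
    if not members:
        warnings.warn(f"{source_set} is empty", stacklevel=2)
        return []
    p_col = "p_ir_g1_gt_g2" if base == "set-I" else "p_ir_g2_gt_g1"
    df = pd.DataFrame(
        {
            "p": sa.table.loc[members, p_col],
            "abs_lr": log2_ratio.reindex(members).abs().fillna(0.0),
        }
    )
    ranked = df.reset_index(names="transcript_id").sort_values(
        ["p", "abs_lr", "transcript_id"], ascending=[True, False, True]
    )["transcript_id"].tolist()
    return ranked[:n]


def _parse_set_label(label: str) -> tuple[str, str | None]:
    if label in ("set-I", "set-II"):
        return label, None
    for base in ("set-II", "set-I"):  # longest prefix first
        if label.startswith(base) and label[len(base):] in ("A", "B", "C"):
            return base, label[len(base):]
    raise ValueError(f"unknown set label {label!r}")


@dataclass
class HeatmapMatrix:
    """Row-standardized TPM matrix with a fixed sample-block column order."""

    values: pd.DataFrame  # transcripts x samples, Z scores
    metric: str  # e.g. "intron-TPM" or "transcript-TPM"
    sample_order: list[str]


def heatmap_sample_order(
    metadata: pd.DataFrame,
    control_group: str,
    case_group: str,
    subgroup_order: Sequence[str] = ("M", "U"),
) -> list[str]:
    """Column order: control block first, then each case subgroup block in turn.

    ``metadata`` is indexed by sample id with ``group`` and (for cases)
    ``subgroup`` columns. Order within a block is the metadata row order.
    """
    order = metadata.index[metadata["group"] == control_group].tolist()
    for sub in subgroup_order:
        order += metadata.index[
            (metadata["group"] == case_group) & (metadata.get("subgroup") == sub)
        ].tolist()
    leftover = metadata.index[
        (metadata["group"] == case_group)
        & ~metadata.index.isin(order)
    ].tolist()
    return order + leftover


def zscore_rows(
    tpm: pd.DataFrame,
    transcripts: Sequence[str],
    sample_order: Sequence[str],
    metric: str = "TPM",
) -> HeatmapMatrix:
    """Standardize each transcript row to mean 0 / sd 1 (sample sd, n-1).

    Constant rows become all-zero. Columns are emitted in ``sample_order``
    regardless of the input column order; unknown samples raise.
    """
    missing = [s for s in sample_order if s not in tpm.columns]
    if missing:
        raise KeyError(f"samples not in matrix: {missing[:5]}")
    sub = tpm.loc[list(transcripts), list(sample_order)].astype(float)
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    z = sub.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return HeatmapMatrix(values=z, metric=metric, sample_order=list(sample_order))


def volcano(
    ir: IRTable,
    tpm_transcript: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series | None = None,
    epsilon: float | None = None,
) -> pd.DataFrame:
    """Volcano coordinates per transcript.

    x       log2 of the between-group ratio of intron/exon-ratio summaries
            (positive: more IR in group 1);
    y_p     -log10 of the two-sided rank-test p comparing per-sample
            intron/exon ratios between the groups (the plotted ordinate);
    y_expr  log10 of the between-group transcript-expression fold change
            (median TPM, pseudocounted), used for the quadrant reading;
    quadrant  textual label of the (x, y_expr) sign combination.
    """
    groups = ir.groups if groups is None else (
        pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    )
    eps = ir.epsilon if epsilon is None else epsilon
    g1, g2 = ir.group_order

    shared = ir.ratios.index.intersection(tpm_transcript.index)
    ratio_p = _screen_frame(
        ir.ratios.loc[shared], groups, ir.group_order, "ratio", two_sided=True
    )["p_ratio_two_sided"]

    expr = tpm_transcript.loc[shared, groups.index]
    m1 = expr[groups.index[groups == g1]].median(axis=1)
    m2 = expr[groups.index[groups == g2]].median(axis=1)
    y_expr = np.log10((m1 + eps) / (m2 + eps))
    x = ir.log2_ratio.reindex(shared)

    quadrant = np.select(
        [
            (x > 0) & (y_expr > 0),
            (x > 0) & (y_expr < 0),
            (x < 0) & (y_expr > 0),
            (x < 0) & (y_expr < 0),
        ],
        [
            f"more IR & more expression in {g1}",
            f"more IR in {g1}, more expression in {g2}",
            f"more IR in {g2}, more expression in {g1}",
            f"more IR & more expression in {g2}",
        ],
        default="on axis",
    )
    return pd.DataFrame(
        {
            "x_log2_ir_ratio": x,
            "y_p": -np.log10(ratio_p.clip(lower=1e-300)),
            "y_expr_log10_fc": y_expr,
            "quadrant": quadrant,
        },
        index=shared,
    )


def quadrant_counts(ir: IRTable) -> dict:
    """Transcripts above / on / below the identity line of group IR summaries.

    'Above' means the group-1 summary ratio strictly exceeds the group-2
    summary (the identity line is where IR is equal in both groups, per the
    scatter's own definition). Also reports percentages of the off-diagonal
    total and an auxiliary OLS fit of group-1 on group-2 log2 summaries.
    """
    g1, g2 = ir.group_order
    s1 = ir.group_summary[g1]
    s2 = ir.group_summary[g2]
    above = int((s1 > s2).sum())
    below = int((s1 < s2).sum())
    on = int((s1 == s2).sum())
    off = above + below
    x = np.log2(s2.to_numpy(dtype=float))
    y = np.log2(s1.to_numpy(dtype=float))
    finite = np.isfinite(x) & np.isfinite(y)
    if finite.sum() >= 2 and np.ptp(x[finite]) > 0:
        slope, intercept = np.polyfit(x[finite], y[finite], 1)
    else:
        slope, intercept = float("nan"), float("nan")
    return {
        "above": above,
        "on": on,
        "below": below,
        "pct_above": 100.0 * above / off if off else 0.0,
        "pct_below": 100.0 * below / off if off else 0.0,
        "ols_slope": float(slope),
        "ols_intercept": float(intercept),
    }
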