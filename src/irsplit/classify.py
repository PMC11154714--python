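"""Directional rank-test screens and the six-set IR/expression classification.

Transcripts are first screened on intronic TPM with two one-sided Wilcoxon
rank-sum (Mann-Whitney) tests, one per direction. Benjamini-Hochberg control
at the 5% level per screen yields set-I (higher intronic signal in group 1)
and set-II (higher in group 2). Within either set, whole-transcript TPM
screens assign the expression subset: A (over-expressed in group 1), B
(under-expressed in group 1), or C (no expression difference, two-sided
p > alpha). Transcripts rejecting an IR screen but fitting none of the three
subset rules are reported as unassigned rather than forced into C.

The two directional screens cannot both reject one transcript at any level
below 0.5, so set-I and set-II are disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 12  # exact rank-sum enumeration below this total sample size


def filter_expressed(
    tpm_transcript: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    threshold_fraction: float = 0.60,
) -> list[str]:
    """Transcripts detected (TPM > 0) in at least ``threshold_fraction`` of
    the samples of EACH group separately (inclusive boundary).
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError(
            f"threshold_fraction must be in (0, 1], got {threshold_fraction}"
        )
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    keep = pd.Series(True, index=tpm_transcript.index)
    for g in groups.unique():
        cols = groups.index[groups == g]
        if len(cols) == 0:
            raise ValueError(f"group {g!r} has no samples")
        frac = (tpm_transcript[cols] > 0).mean(axis=1)
        # guard the inclusive boundary against float representation of the threshold
        keep &= frac >= threshold_fraction - 1e-12
    return tpm_transcript.index[keep].tolist()


def rank_test_one_sided(
    a: Sequence[float], b: Sequence[float], direction: str = "greater"
) -> float:
    """One-sided Wilcoxon rank-sum p-value for H1: a stochastically > (or <) b.

    Uses exact enumeration when the pooled sample size is at most 12 and the
    data carry no ties; otherwise the normal approximation with tie-corrected
    variance and continuity correction. Two identical constant samples give
    p = 1 (no directional evidence).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=direction, method=method)
    return float(res.pvalue)


def _screen_frame(
    values: pd.DataFrame,
    groups: pd.Series,
    group_order: tuple[str, str],
    prefix: str,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Row-wise directional Mann-Whitney p-values for a transcript x sample matrix."""
    g1, g2 = group_order
    a = values[groups.index[groups == g1]].to_numpy(dtype=float)
    b = values[groups.index[groups == g2]].to_numpy(dtype=float)
    n = a.shape[1] + b.shape[1]
    out = {}
    if n <= EXACT_MAX_N:
        out[f"p_{prefix}_g1_gt_g2"] = [
            rank_test_one_sided(a[i], b[i], "greater") for i in range(a.shape[0])
        ]
        out[f"p_{prefix}_g2_gt_g1"] = [
            rank_test_one_sided(a[i], b[i], "less") for i in range(a.shape[0])
        ]
        if two_sided:
            out[f"p_{prefix}_two_sided"] = [
                float(
                    stats.mannwhitneyu(a[i], b[i], alternative="two-sided").pvalue
                )
                for i in range(a.shape[0])
            ]
    else:
        for alt, col in (
            ("greater", f"p_{prefix}_g1_gt_g2"),
            ("less", f"p_{prefix}_g2_gt_g1"),
        ) + ((("two-sided", f"p_{prefix}_two_sided"),) if two_sided else ()):
            res = stats.mannwhitneyu(
                a, b, alternative=alt, method="asymptotic", axis=-1
            )
            out[col] = np.asarray(res.pvalue, dtype=float)
    return pd.DataFrame(out, index=values.index)


@dataclass
class ScreenResult:
    """Per-transcript p and q values of the four directional screens."""

    table: pd.DataFrame  # p_ir_*, q_ir_*, p_expr_*, q_expr_*, p_expr_two_sided
    n_g1: int
    n_g2: int
    group_order: tuple[str, str]
    fdr_level: float = 0.05

    @property
    def transcripts(self) -> list[str]:
        return list(self.table.index)


def bh_adjust(pvals: Sequence[float], level: float = 0.05):
    """Benjamini-Hochberg step-up: returns (q-values, rejection flags).

    q-values are monotone in sorted-p order; rejection iff q <= level.
    Empty input returns empty arrays.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return q, reject


def run_screens(
    intronic: pd.DataFrame,
    transcript: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    group_order: tuple[str, str] | None = None,
    fdr_level: float = 0.05,
) -> ScreenResult:
    """Run the intronic and whole-transcript directional screens with BH adjustment.

    ``intronic`` and ``transcript`` are transcript x sample TPM frames sharing
    an index. BH q-values are computed per screen across all transcripts.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    shared = intronic.index.intersection(transcript.index)
    intronic = intronic.loc[shared]
    transcript = transcript.loc[shared]
    if group_order is None:
        ordered = groups.drop_duplicates().tolist()
        if len(ordered) != 2:
            raise ValueError(f"expected exactly 2 groups, got {ordered}")
        group_order = (ordered[0], ordered[1])
    groups = groups[groups.isin(group_order)]

    ir = _screen_frame(intronic, groups, group_order, "ir")
    expr = _screen_frame(transcript, groups, group_order, "expr", two_sided=True)
    table = pd.concat([ir, expr], axis=1)
    for col in (
        "p_ir_g1_gt_g2",
        "p_ir_g2_gt_g1",
        "p_expr_g1_gt_g2",
        "p_expr_g2_gt_g1",
    ):
        table[col.replace("p_", "q_", 1)], _ = bh_adjust(table[col], fdr_level)
    g1, g2 = group_order
    return ScreenResult(
        table=table,
        n_g1=int((groups == g1).sum()),
        n_g2=int((groups == g2).sum()),
        group_order=group_order,
        fdr_level=fdr_level,
    )


@dataclass
class SetAssignment:
    """Per-transcript six-set labels with the thresholds that produced them."""

    table: pd.DataFrame  # columns: ir_set, expr_subset (+ p/q columns carried over)
    alpha: float
    fdr_level: float
    group_order: tuple[str, str]

    def members(self, ir_set: str, expr_subset: str | None = None) -> list[str]:
        mask = self.table["ir_set"] == ir_set
        if expr_subset is not None:
            mask &= self.table["expr_subset"] == expr_subset
        return self.table.index[mask].tolist()

    def set_counts(self) -> pd.DataFrame:
        """Counts of {set-I, set-II} x {A, B, C, unassigned}."""
        sub = self.table[self.table["ir_set"] != "none"]
        return (
            sub.groupby(["ir_set", "expr_subset"])
            .size()
            .unstack(fill_value=0)
            .reindex(index=["set-I", "set-II"], fill_value=0)
            .reindex(columns=["A", "B", "C", "unassigned"], fill_value=0)
        )


def classify_sets(
    sr: ScreenResult,
    alpha: float = 0.05,
    fdr_level: float = 0.05,
    expr_mode: str = "fdr",
) -> SetAssignment:
    """Assign each transcript its IR set and expression subset.

    set-I / set-II come from BH rejection of the directional intronic screens.
    Subsets A/B come from the directional expression screens — BH-adjusted at
    ``fdr_level`` by default, or raw p < alpha with ``expr_mode='raw'``.
    Subset C requires two-sided expression p > alpha (raw, mirroring the
    asymmetric rule of the original analysis). Remaining IR-set members are
    'unassigned'.
    """
    t = sr.table.copy()
    set_i = t["q_ir_g1_gt_g2"] <= fdr_level
    set_ii = t["q_ir_g2_gt_g1"] <= fdr_level
    both = set_i & set_ii
    if both.any():  # impossible for alpha <= 0.25; defensive
        raise RuntimeError("directional screens rejected both ways")

    if expr_mode == "fdr":
        a_hit = t["q_expr_g1_gt_g2"] <= fdr_level
        b_hit = t["q_expr_g2_gt_g1"] <= fdr_level
    elif expr_mode == "raw":
        a_hit = t["p_expr_g1_gt_g2"] < alpha
        b_hit = t["p_expr_g2_gt_g1"] < alpha
    else:
        raise ValueError(f"expr_mode must be 'fdr' or 'raw', got {expr_mode!r}")
    c_hit = t["p_expr_two_sided"] > alpha

    ir_set = np.where(set_i, "set-I", np.where(set_ii, "set-II", "none"))
    expr_subset = np.select(
        [ir_set == "none", a_hit, b_hit, c_hit],
        ["", "A", "B", "C"],
        default="unassigned",
    )
    t["ir_set"] = ir_set
    t["expr_subset"] = expr_subset
    return SetAssignment(
        table=t, alpha=alpha, fdr_level=fdr_level, group_order=sr.group_order
    )


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (87.5 -> 88)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def subset_percentages(counts: Sequence[float]) -> list[int]:
    """Percentages of each subset within its set, rounded half-up to integers."""
    total = float(sum(counts))
    if total == 0:
        return [0 for _ in counts]
    return [round_half_up(100.0 * c / total) for c in counts]


@dataclass
class ContingencyResult:
    """Association between IR direction and expression direction."""

    table_2x3: pd.DataFrame  # {set-I, set-II} x {A, B, C}
    chi2_stat: float
    chi2_p: float
    table_2x2: pd.DataFrame  # {set-I, set-II} x {A, B}
    odds_ratio: float
    fisher_p: float
    haldane_corrected: bool
    subset_percentages: pd.DataFrame  # per set, integer % of A/B/C

    def to_dict(self) -> dict:
        return {
            "table_2x3": self.table_2x3.to_dict(),
            "chi2_stat": self.chi2_stat,
            "chi2_p": self.chi2_p,
            "table_2x2": self.table_2x2.to_dict(),
            "odds_ratio": self.odds_ratio,
            "fisher_p": self.fisher_p,
            "haldane_corrected": self.haldane_corrected,
            "subset_percentages": self.subset_percentages.to_dict(),
        }


def sample_odds_ratio(table: np.ndarray) -> tuple[float, bool]:
    """Cross-product odds ratio ad/bc; Haldane-Anscombe +0.5 on any zero cell."""
    t = np.asarray(table, dtype=float)
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    return float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0])), corrected


def contingency(sa: SetAssignment) -> ContingencyResult:
    """2x3 chi-square and 2x2 Fisher association of IR set vs expression subset.

    Chi-square is Pearson's without continuity correction on the
    {set-I, set-II} x {A, B, C} counts; Fisher's exact test and the sample
    odds ratio use the {A, B} columns only. Unassigned transcripts are
    excluded from the tables.
    """
    counts = sa.set_counts()[["A", "B", "C"]]
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("both set-I and set-II must be non-empty")
    chi2, chi2_p, _, _ = stats.chi2_contingency(
        counts.to_numpy(), correction=False
    )[:4]
    t22 = counts[["A", "B"]]
    odds, corrected = sample_odds_ratio(t22.to_numpy())
    _, fisher_p = stats.fisher_exact(t22.to_numpy(), alternative="two-sided")
    pct = pd.DataFrame(
        {
            s: subset_percentages(counts.loc[s].tolist())
            for s in counts.index
        },
        index=counts.columns,
    ).T
    return ContingencyResult(
        table_2x3=counts,
        chi2_stat=float(chi2),
        chi2_p=float(chi2_p),
        table_2x2=t22,
        odds_ratio=odds,
        fisher_p=float(fisher_p),
        haldane_corrected=corrected,
        subset_percentages=pct,
    )
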