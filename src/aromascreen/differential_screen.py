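"""Pairwise discriminating-volatile screen and ROC marker validation.

A compound discriminates a target cultivar from a reference when, in that
pairwise comparison, it passes all three strict thresholds

    VIP > 1.0,   FC > 1.2 or FC < 0.8,   BH-FDR q < 0.05

where FC is the ratio of mean contents (target over reference), the
p-value comes from a two-sample t-test on the replicates, and VIP comes
from a two-class OPLS-DA of the same comparison. BH adjustment runs
within each comparison over its testable compounds.

The screen defaults to the pooled-variance (Student) t-test: with
triplicate groups, Welch's Satterthwaite correction can halve the
degrees of freedom, and after FDR adjustment over tens of compounds a
clear two-fold effect at 5% replicate CV then fails the q < 0.05 cut in
roughly a third of runs. The pooled test keeps its four degrees of
freedom and recovers such effects almost always; Welch's variant is
available for sensitivity checks via ``t_test="welch"``.

Degenerate inputs are handled explicitly: a compound undetected in all
replicates of both groups is *untestable* (not "not significant"); a
reference mean of zero with a detected target gives FC = +inf, which is a
present/absent call and satisfies FC > 1.2.

ROC validation treats a compound's replicate contents as a diagnostic
score for "target cultivar vs rest"; the curve is a threshold sweep with
half-steps at ties, and the AUC equals the Mann-Whitney U statistic
divided by n1*n2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .multivariate import opls_da, zscore
from .volatile_table import ContentMatrix

__all__ = [
    "ScreenConfig",
    "DiffTable",
    "ROCCurve",
    "welch_t",
    "student_t",
    "bh_fdr",
    "fold_change",
    "volcano_classify",
    "discriminating_screen",
    "venn_intersections",
    "discriminating_key_odorants",
    "roc_auc",
]

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "not_significant"
STATUS_UNTESTABLE = "untestable"


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the discriminating-volatile rule (all strict)."""

    vip_min: float = 1.0
    fc_hi: float = 1.2
    fc_lo: float = 0.8
    q_max: float = 0.05
    oav_min: float = 1.0

    def __post_init__(self) -> None:
        if not self.fc_lo < 1.0 < self.fc_hi:
            raise ValueError("fold-change thresholds must straddle 1")
        if not 0.0 < self.q_max < 1.0:
            raise ValueError("q_max must lie in (0, 1)")


@dataclass
class DiffTable:
    """Per-compound statistics of one pairwise comparison."""

    ref: str
    target: str
    table: pd.DataFrame  # indexed by compound_id
    config: ScreenConfig = field(default_factory=ScreenConfig)

    def discriminating(self) -> set[str]:
        mask = self.table["status"].isin([STATUS_UP, STATUS_DOWN])
        return set(self.table.index[mask])


@dataclass
class ROCCurve:
    """Threshold-sweep ROC curve with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


# ---------------------------------------------------------------------------
# elementary statistics


def welch_t(x, y) -> tuple[float, float] | None:
    """Welch's unequal-variance two-sided t-test.

    Returns (t, p), or None when the test is degenerate (both groups
    constant at different values, so the Satterthwaite df collapses).
    Both groups constant and *equal* is a well-defined no-difference
    case: (0.0, 1.0).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        return None
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return (0.0, 1.0) if x.mean() == y.mean() else None
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def student_t(x, y) -> tuple[float, float] | None:
    """Pooled-variance two-sided t-test; degenerate cases as in welch_t."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        return None
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return (0.0, 1.0) if x.mean() == y.mean() else None
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fold_change(mean_ref: float, mean_int: float) -> float | None:
    """Ratio of group means, target over reference.

    Zero reference with a detected target is a present/absent contrast
    (FC = +inf); both means zero is untestable (None).
    """
    if mean_ref < 0 or mean_int < 0:
        raise ValueError("means must be non-negative")
    if mean_ref == 0:
        return math.inf if mean_int > 0 else None
    return mean_int / mean_ref


def volcano_classify(
    q: float, fc: float | None, vip: float, config: ScreenConfig = ScreenConfig()
) -> str:
    """Status of one compound under the strict three-way threshold rule."""
    if fc is None or not np.isfinite(q):
        return STATUS_UNTESTABLE
    if q < config.q_max and vip > config.vip_min:
        if fc > config.fc_hi:
            return STATUS_UP
        if fc < config.fc_lo:
            return STATUS_DOWN
    return STATUS_NS


# ---------------------------------------------------------------------------
# the screen


def discriminating_screen(
    matrix: ContentMatrix,
    ref: str,
    target: str,
    config: ScreenConfig = ScreenConfig(),
    n_ortho: int = 1,
    t_test: str = "student",
) -> DiffTable:
    """Run the full pairwise screen of ``target`` against ``ref``.

    Per compound: two-sample t on replicate contents (n.d. as 0; pooled
    variance by default, ``t_test="welch"`` for the unequal-variance
    variant), BH adjustment across this comparison's testable compounds,
    fold change on replicate means, VIP from a two-class OPLS-DA of the
    z-scored replicate matrix.
    """
    if t_test not in ("student", "welch"):
        raise ValueError("t_test must be 'student' or 'welch'")
    t_fn = student_t if t_test == "student" else welch_t
    for cv in (ref, target):
        if cv not in matrix.cultivars:
            raise ValueError(f"cultivar {cv!r} not present in the content matrix")
    x_ref = matrix.replicates(ref)
    x_tgt = matrix.replicates(target)
    compounds = matrix.compounds

    # VIP from the two-class OPLS-DA of this comparison
    X = np.vstack([x_ref.values.T, x_tgt.values.T])  # samples x compounds
    y = [ref] * x_ref.shape[1] + [target] * x_tgt.shape[1]
    vips = opls_da(zscore(X), y, n_ortho=n_ortho).vip

    rows = []
    for idx, cid in enumerate(compounds):
        xr = x_ref.loc[cid].to_numpy(float)
        xt = x_tgt.loc[cid].to_numpy(float)
        mean_ref, mean_int = float(xr.mean()), float(xt.mean())
        fc = fold_change(mean_ref, mean_int)
        tp = t_fn(xr, xt)
        rows.append(
            {
                "compound_id": cid,
                "mean_ref": mean_ref,
                "mean_int": mean_int,
                "fc": np.nan if fc is None else fc,
                "t_stat": np.nan if tp is None else tp[0],
                "p_value": np.nan if tp is None else tp[1],
                "vip": float(vips[idx]),
            }
        )
    table = pd.DataFrame(rows).set_index("compound_id")

    # a compound absent from both groups has no contrast to test and
    # stays out of the BH pool entirely
    testable = table["p_value"].notna() & table["fc"].notna()
    q = pd.Series(np.nan, index=table.index)
    if testable.any():
        q.loc[testable] = bh_fdr(table.loc[testable, "p_value"].to_numpy())
    table["q_value"] = q

    # display log2 fold change with a pseudocount of half the smallest
    # nonzero mean, so present/absent compounds render on a volcano plot
    nonzero = table[["mean_ref", "mean_int"]].to_numpy()
    nonzero = nonzero[nonzero > 0]
    eps = nonzero.min() / 2.0 if nonzero.size else 1.0
    table["log2fc"] = np.log2((table["mean_int"] + eps) / (table["mean_ref"] + eps))

    status = []
    for cid, row in table.iterrows():
        fc = None if np.isnan(row["fc"]) else row["fc"]
        if np.isnan(row["q_value"]):
            status.append(STATUS_UNTESTABLE)
        else:
            status.append(volcano_classify(row["q_value"], fc, row["vip"], config))
    table["status"] = status
    return DiffTable(ref=ref, target=target, table=table, config=config)


def venn_intersections(tables: list[DiffTable]) -> dict[str, frozenset[str]]:
    """Per compound, the set of comparisons in which it discriminates.

    Comparisons are keyed "REF_vs_TARGET". Compounds discriminating in no
    comparison are omitted, so region counts sum to the union size.
    """
    universe = None
    for t in tables:
        ids = set(t.table.index)
        if universe is None:
            universe = ids
        elif ids != universe:
            raise ValueError("all comparisons must share one compound universe")
    membership: dict[str, set[str]] = {}
    for t in tables:
        key = f"{t.ref}_vs_{t.target}"
        for cid in t.discriminating():
            membership.setdefault(cid, set()).add(key)
    return {cid: frozenset(v) for cid, v in membership.items()}


def discriminating_key_odorants(
    tables: list[DiffTable] | dict[str, frozenset[str]], key_set: set[str]
) -> set[str]:
    """Key odor-active compounds that discriminate in >= 1 comparison."""
    if isinstance(tables, dict):
        discriminating = set(tables)
    else:
        discriminating = set()
        for t in tables:
            discriminating |= t.discriminating()
    return discriminating & key_set


# ---------------------------------------------------------------------------
# ROC


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve of ``scores`` for the positive class (labels truthy).

    Tied scores advance TP and FP jointly (half-step convention), which
    makes the trapezoidal AUC equal the Mann-Whitney U statistic over
    n1*n2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label groups must be non-empty")

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # collapse tied scores into single sweep points
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)
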