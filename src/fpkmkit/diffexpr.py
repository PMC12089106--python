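"""Per-gene group-comparison statistics on FPKM matrices.

Implements the small-sample two-group tests (Mann-Whitney U with an exact
permutation distribution at small combined n, Welch's t), a Welch /
Brown-Forsythe heteroscedastic ANOVA with control-referenced post-hoc
comparisons, fold-change computation on raw FPKM group means, the
``*``/``**``/``***`` star-label convention, a significant-fraction summary,
and deterministic p-value / effect-size ranking.

Notes on conventions
--------------------
* Fold change is always reported as a ratio >= 1, with a separate
  ``direction`` flag giving the orientation of group *b* relative to the
  reference group *a*.  A zero mean in either group makes the ratio
  undefined and raises :class:`~fpkmkit.errors.UndefinedFoldError`
  (table-level drivers record the flag instead of an infinity).
* Two-sided Mann-Whitney p is defined as ``min(1, 2 x smaller one-sided
  tail)``; the exact route is taken when ``n_x + n_y <= 12`` and the pooled
  data carry no ties.
* No multiple-testing correction is applied by default; raw per-gene
  p-values are reported.  Benjamini-Hochberg is available via
  ``adjust="bh"`` on :func:`compare_groups` as a clearly-labelled extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, DegenerateVarianceError, UndefinedFoldError
from .expression import ExpressionMatrix, SampleTable

EXACT_MWU_MAX_N = 12  # combined-n cutoff for the exact permutation route


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def fold_change(mean_a: float, mean_b: float) -> tuple[float, str]:
    """Ratio of the larger to the smaller group mean, plus orientation.

    ``mean_a`` is the reference (control) group.  The returned direction is
    that of *b* relative to *a*: ``"down"`` when ``mean_b < mean_a``,
    ``"up"`` when greater, ``"unchanged"`` when equal.
    """
    if mean_a < 0 or mean_b < 0:
        raise ArgumentError(f"negative group mean: ({mean_a}, {mean_b})")
    if mean_a == 0 and mean_b == 0:
        raise UndefinedFoldError("fold change undefined: both group means are zero")
    if mean_a == 0 or mean_b == 0:
        raise UndefinedFoldError(
            f"fold change undefined: zero group mean in ({mean_a}, {mean_b})"
        )
    if mean_b < mean_a:
        return mean_a / mean_b, "down"
    if mean_b > mean_a:
        return mean_b / mean_a, "up"
    return 1.0, "unchanged"


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["exact", "approx", "auto"] = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    ``auto`` uses the full exact permutation distribution when
    ``n_x + n_y <= 12`` and the pooled sample has no ties, otherwise the
    normal approximation with tie and continuity corrections.
    Returns ``(U, p_two_sided)`` with U counted for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ArgumentError("both samples must be non-empty")
    if mode not in ("exact", "approx", "auto"):
        raise ArgumentError(f"unknown mode {mode!r}")
    if mode == "auto":
        pooled = np.concatenate([x, y])
        has_ties = np.unique(pooled).size < pooled.size
        mode = "exact" if (pooled.size <= EXACT_MWU_MAX_N and not has_ties) else "approx"
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    for name, arr in (("x", x), ("y", y)):
        if arr.size < 2:
            raise ArgumentError(f"group {name} needs >= 2 values, got {arr.size}")
        if np.var(arr, ddof=1) == 0:
            raise DegenerateVarianceError(f"group {name} has zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Heteroscedastic three-group ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    """Welch and Brown-Forsythe omnibus p-values plus control-referenced
    pairwise comparisons (adjusted)."""

    p_welch: float
    p_brown_forsythe: float
    per_comparison: dict[str, float]
    per_comparison_unadjusted: dict[str, float]
    method: str


def _welch_anova(groups: list[np.ndarray]) -> float:
    k = len(groups)
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    a = np.sum(w * (m - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    b = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f = a / b
    df2 = (k**2 - 1) / (3 * lam)
    return float(stats.f.sf(f, k - 1, df2))


def _brown_forsythe_anova(groups: list[np.ndarray]) -> float:
    # Brown-Forsythe F* on means (heteroscedastic ANOVA, not the spread test)
    k = len(groups)
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    big_n = n.sum()
    grand = np.concatenate(groups).mean()
    num = np.sum(n * (m - grand) ** 2)
    denom_terms = (1 - n / big_n) * v
    denom = denom_terms.sum()
    f = num / denom
    c = denom_terms / denom
    df2 = 1.0 / np.sum(c**2 / (n - 1))
    return float(stats.f.sf(f, k - 1, df2))


def bf_welch_anova(
    groups: Mapping[str, Sequence[float]],
    control: str = "control",
    method: Literal["t3", "games-howell"] = "t3",
) -> AnovaResult:
    """Heteroscedastic omnibus tests plus control-referenced post-hoc.

    ``method="t3"`` adjusts each Welch pairwise p-value across the family of
    control-referenced comparisons via the independence form of the
    studentized-maximum-modulus correction, ``p_adj = 1 - (1 - p)^m``
    (Dunnett-T3 style).  ``method="games-howell"`` uses the studentized
    range on Welch standard errors instead.
    """
    if len(groups) < 3:
        raise ArgumentError(
            "need >= 3 groups; use welch_t or mann_whitney_u for two groups"
        )
    if control not in groups:
        raise ArgumentError(f"control group {control!r} absent from input")
    arrays = {lbl: np.asarray(v, dtype=float) for lbl, v in groups.items()}
    for lbl, arr in arrays.items():
        if arr.size < 2:
            raise ArgumentError(f"group {lbl!r} needs >= 2 values")
        if np.var(arr, ddof=1) == 0:
            raise DegenerateVarianceError(f"group {lbl!r} has zero variance")
    glist = list(arrays.values())
    p_w = _welch_anova(glist)
    p_bf = _brown_forsythe_anova(glist)

    others = [lbl for lbl in arrays if lbl != control]
    m_comp = len(others)
    k = len(arrays)
    ctrl = arrays[control]
    raw: dict[str, float] = {}
    adj: dict[str, float] = {}
    for lbl in others:
        contrast = f"{lbl}-vs-{control}"
        _, _, p = welch_t(ctrl, arrays[lbl])
        raw[contrast] = p
        if method == "t3":
            adj[contrast] = float(min(1.0, 1.0 - (1.0 - p) ** m_comp))
        elif method == "games-howell":
            other = arrays[lbl]
            se2 = ctrl.var(ddof=1) / ctrl.size + other.var(ddof=1) / other.size
            q = abs(ctrl.mean() - other.mean()) / np.sqrt(se2 / 2.0)
            df = se2**2 / (
                (ctrl.var(ddof=1) / ctrl.size) ** 2 / (ctrl.size - 1)
                + (other.var(ddof=1) / other.size) ** 2 / (other.size - 1)
            )
            adj[contrast] = float(stats.studentized_range.sf(q, k, df))
        else:
            raise ArgumentError(f"unknown post-hoc method {method!r}")
    return AnovaResult(
        p_welch=p_w,
        p_brown_forsythe=p_bf,
        per_comparison=adj,
        per_comparison_unadjusted=raw,
        method=method,
    )


# ---------------------------------------------------------------------------
# Labels, summaries, ranking
# ---------------------------------------------------------------------------

def star_label(p: float) -> str:
    """``""``/``*``/``**``/``***`` at the strict 0.05 / 0.01 / 0.005 cuts."""
    if not 0.0 <= p <= 1.0:
        raise ArgumentError(f"p-value outside [0, 1]: {p}")
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class SignificanceSummary:
    n_total: int
    n_significant: int
    alpha: float

    @property
    def proportion_percent(self) -> float:
        if self.n_total == 0:
            return 0.0
        return round(100.0 * self.n_significant / self.n_total, 1)


def significance_summary(p_values: Sequence[float], alpha: float = 0.05) -> SignificanceSummary:
    """Count p-values strictly below ``alpha``; percentage to one decimal."""
    if not 0.0 < alpha < 1.0:
        raise ArgumentError(f"alpha must be in (0, 1), got {alpha}")
    p = np.asarray(p_values, dtype=float)
    return SignificanceSummary(
        n_total=int(p.size), n_significant=int(np.sum(p < alpha)), alpha=alpha
    )


def rank_genes(results: pd.DataFrame) -> pd.DataFrame:
    """Sort a per-gene results table by p-value and effect size.

    Stable ordering: ascending ``p_value``, ties by descending
    ``fold_change`` (undefined folds sort last within a p tie), remaining
    ties by ``gene_id``.  Adds a 1-based ``rank`` column.
    """
    for col in ("gene_id", "p_value", "fold_change"):
        if col not in results.columns:
            raise ArgumentError(f"results table missing column {col!r}")
    out = results.copy()
    fc_key = out["fold_change"].fillna(-np.inf)
    order = np.lexsort(
        (out["gene_id"].to_numpy(), -fc_key.to_numpy(), out["p_value"].to_numpy())
    )
    out = out.iloc[order].reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (extension; not applied by default)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Matrix-level driver
# ---------------------------------------------------------------------------

def compare_groups(
    matrix: ExpressionMatrix,
    metadata: SampleTable,
    group_a: str = "control",
    group_b: str = "AD",
    test: Literal["welch", "mannwhitney"] = "welch",
    adjust: Literal["none", "bh"] = "none",
) -> pd.DataFrame:
    """Per-gene two-group comparison over every gene in the matrix.

    Group means and fold changes are computed on raw FPKM (arithmetic
    means); the test is applied to the raw per-sample values.  Genes whose
    fold change is undefined (a zero group mean) carry ``NaN`` in
    ``fold_change`` and a direction inferred from the means.
    """
    metadata.validate_against(matrix)
    in_matrix = set(matrix.sample_ids)
    samples_a = [s for s in metadata.samples_in_group(group_a) if s in in_matrix]
    samples_b = [s for s in metadata.samples_in_group(group_b) if s in in_matrix]
    if not samples_a or not samples_b:
        raise ArgumentError(
            f"empty group in contrast {group_b}-vs-{group_a}: "
            f"n_a={len(samples_a)}, n_b={len(samples_b)}"
        )
    idx_a = [matrix.sample_ids.index(s) for s in samples_a]
    idx_b = [matrix.sample_ids.index(s) for s in samples_b]
    contrast = f"{group_b}-vs-{group_a}"

    rows = []
    for gi, gene in enumerate(matrix.gene_ids):
        va = matrix.values[gi, idx_a]
        vb = matrix.values[gi, idx_b]
        mean_a = float(va.mean())
        mean_b = float(vb.mean())
        try:
            fc, direction = fold_change(mean_a, mean_b)
        except UndefinedFoldError:
            fc = np.nan
            direction = (
                "unchanged" if mean_a == mean_b else ("down" if mean_b < mean_a else "up")
            )
        if test == "welch":
            try:
                stat, _, p = welch_t(va, vb)
            except DegenerateVarianceError:
                stat, p = np.nan, 1.0
        elif test == "mannwhitney":
            stat, p = mann_whitney_u(va, vb, mode="auto")
        else:
            raise ArgumentError(f"unknown test {test!r}")
        rows.append(
            {
                "gene_id": gene,
                "contrast": contrast,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "fold_change": fc,
                "direction": direction,
                "test_name": test,
                "statistic": stat,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["p_adjusted"] = benjamini_hochberg(out["p_value"].to_numpy())
    elif adjust != "none":
        raise ArgumentError(f"unknown adjustment {adjust!r}")
    out["star_label"] = [star_label(p) for p in out["p_value"]]
    return out


def write_results(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
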