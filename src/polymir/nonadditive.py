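"""Mid-parent non-additivity calls and five-way expression-pattern classes.

In a hybrid/parents trio the additive expectation for any feature is the
mid-parent value MPV = (P1 + P2) / 2.  A feature whose hybrid expression
departs from the MPV (|log2 fold change| > ``lfc`` at Benjamini-Hochberg
q < ``alpha``) is called non-additive; non-additive features are then
classified by where the hybrid sits relative to the two parents:

========  =====================================================
HP        significantly higher than both parents
LP        significantly lower than both parents
CT44      statistically close to parent 1, different from parent 2
CT45      statistically close to parent 2, different from parent 1
BP        strictly between two significantly different parents
========  =====================================================

Features matching none of the listed patterns are reported as
``unclassified`` rather than forced into a bucket.

All tests are two-sided Welch t-tests on log2(RPM + 1); the hybrid-vs-MPV
test uses mid-parent pseudo-replicates built by pairing parental
replicates by index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import TrioCountMatrix

CATEGORIES = ("HP", "LP", "CT44", "CT45", "BP", "unclassified")

COMPARISONS = {
    "H_vs_P1": ("H", "P1"),
    "H_vs_P2": ("H", "P2"),
    "P1_vs_P2": ("P1", "P2"),
}


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_rpm(matrix: TrioCountMatrix) -> TrioCountMatrix:
    """Attach a reads-per-million layer (each column scaled to sum 1e6)."""
    sums = matrix.counts.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero-sum sample column(s): {list(zero.index)}")
    rpm = matrix.counts / sums * 1e6
    return TrioCountMatrix(counts=matrix.counts, roles=dict(matrix.roles), rpm=rpm)


# ---------------------------------------------------------------------------
# pairwise differential tests
# ---------------------------------------------------------------------------


def _welch_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch t-test p-values on already-logged data.

    Degenerate rows (zero variance in both groups) get p = 1 when the
    group means agree — no evidence either way — and p = 0 when they
    differ, where the t statistic diverges.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    same = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[degenerate & same] = 1.0
    p[degenerate & ~same] = 0.0
    return p


def _bh(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    mask = ~np.isnan(p)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def pairwise_test(
    matrix: TrioCountMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    lfc: float = 1.0,
    require_q: bool = False,
) -> pd.DataFrame:
    """Differential test of one genotype group against another.

    Welch t-test per feature on log2(RPM + 1); log2 fold change is the
    ratio of group mean RPM with a pseudocount of 1; BH correction runs
    across all tested features.  Features with zero counts in both groups
    are excluded from testing (and from the BH denominator) and reported
    as not significant.

    ``require_q`` additionally demands q < alpha (gene mode); the default
    miRNA mode calls significance at p < alpha with |log2FC| > ``lfc``.
    """
    rpm = matrix.rpm_or_raise()
    cols_a = matrix.samples(group_a)
    cols_b = matrix.samples(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"groups {group_a}/{group_b} need >= 2 replicates "
            f"(got {len(cols_a)}/{len(cols_b)})"
        )
    raw_a = matrix.counts[cols_a].to_numpy()
    raw_b = matrix.counts[cols_b].to_numpy()
    tested = (raw_a.sum(axis=1) + raw_b.sum(axis=1)) > 0

    a = np.log2(rpm[cols_a].to_numpy() + 1.0)
    b = np.log2(rpm[cols_b].to_numpy() + 1.0)
    mean_a = rpm[cols_a].to_numpy().mean(axis=1)
    mean_b = rpm[cols_b].to_numpy().mean(axis=1)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    p = np.full(matrix.n_features, np.nan)
    p[tested] = _welch_rows(a[tested], b[tested])
    q = _bh(p)

    significant = tested & (p < alpha) & (np.abs(log2fc) > lfc)
    if require_q:
        significant &= q < alpha
    direction = np.where(
        ~significant, "ns", np.where(log2fc > 0, "up", "down")
    )
    return pd.DataFrame(
        {
            "comparison": f"{group_a}_vs_{group_b}",
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "tested": tested,
            "significant": significant,
            "direction": direction,
        },
        index=matrix.feature_ids,
    )


# ---------------------------------------------------------------------------
# mid-parent value
# ---------------------------------------------------------------------------


def _mpv_replicates(matrix: TrioCountMatrix) -> pd.DataFrame:
    """Mid-parent pseudo-replicates on the RPM scale.

    Parental replicates are paired by sorted replicate index; if the
    parents have unequal replicate numbers the pairing stops at the
    smaller count.
    """
    rpm = matrix.rpm_or_raise()
    p1 = matrix.samples("P1")
    p2 = matrix.samples("P2")
    k = min(len(p1), len(p2))
    vals = (rpm[p1[:k]].to_numpy() + rpm[p2[:k]].to_numpy()) / 2.0
    cols = [f"MPV_{i + 1}" for i in range(k)]
    return pd.DataFrame(vals, index=matrix.feature_ids, columns=cols)


def mid_parent(matrix: TrioCountMatrix, feature: str) -> tuple[np.ndarray, float]:
    """Return (mid-parent pseudo-replicates, mid-parent mean) for a feature.

    The mean is (mean(P1) + mean(P2)) / 2 on the RPM scale, which equals
    the mean of the pseudo-replicates when the parents have matching
    replicate counts.
    """
    rpm = matrix.rpm_or_raise()
    reps = _mpv_replicates(matrix).loc[feature].to_numpy()
    mean = (
        rpm.loc[feature, matrix.samples("P1")].mean()
        + rpm.loc[feature, matrix.samples("P2")].mean()
    ) / 2.0
    return reps, float(mean)


# ---------------------------------------------------------------------------
# additivity and pattern classification
# ---------------------------------------------------------------------------


def classify_additivity(
    matrix: TrioCountMatrix, alpha: float = 0.05, lfc: float = 1.0
) -> pd.DataFrame:
    """Call each feature additive or non-additive against the MPV.

    Non-additive requires |log2(mean_H / mpv_mean)| > ``lfc`` (pseudocount
    1 on RPM) and BH q < ``alpha`` from a Welch t-test of hybrid
    replicates against mid-parent pseudo-replicates.
    """
    rpm = matrix.rpm_or_raise()
    h_cols = matrix.samples("H")
    if len(h_cols) < 2:
        raise ValueError("hybrid group needs >= 2 replicates")
    mpv_reps = _mpv_replicates(matrix).to_numpy()
    h = rpm[h_cols].to_numpy()

    mean_h = h.mean(axis=1)
    mpv_mean = (
        rpm[matrix.samples("P1")].to_numpy().mean(axis=1)
        + rpm[matrix.samples("P2")].to_numpy().mean(axis=1)
    ) / 2.0
    log2fc = np.log2((mean_h + 1.0) / (mpv_mean + 1.0))

    p = _welch_rows(np.log2(h + 1.0), np.log2(mpv_reps + 1.0))
    q = _bh(p)
    nonadditive = (np.abs(log2fc) > lfc) & (q < alpha)
    return pd.DataFrame(
        {
            "mpv": mpv_mean,
            "log2fc_mpv": log2fc,
            "p": p,
            "q": q,
            "additivity": np.where(nonadditive, "non-additive", "additive"),
        },
        index=matrix.feature_ids,
    )


def classify_pattern(
    nonadditive: bool,
    h_vs_p1: pd.Series,
    h_vs_p2: pd.Series,
    p1_vs_p2: pd.Series,
) -> str:
    """Assign one of HP/LP/CT44/CT45/BP/unclassified to a non-additive call.

    ``>``/``<`` mean significantly different in the stated direction and
    ``=`` means not significantly different, all per the pairwise tests.
    Additive features are labelled ``additive``.
    """
    if not nonadditive:
        return "additive"
    up1 = h_vs_p1["significant"] and h_vs_p1["direction"] == "up"
    dn1 = h_vs_p1["significant"] and h_vs_p1["direction"] == "down"
    up2 = h_vs_p2["significant"] and h_vs_p2["direction"] == "up"
    dn2 = h_vs_p2["significant"] and h_vs_p2["direction"] == "down"
    eq1 = not h_vs_p1["significant"]
    eq2 = not h_vs_p2["significant"]

    if up1 and up2:
        return "HP"
    if dn1 and dn2:
        return "LP"
    if eq1 and (up2 or dn2):
        return "CT44"
    if eq2 and (up1 or dn1):
        return "CT45"
    if (up1 and dn2) or (dn1 and up2):
        return "BP"
    return "unclassified"


def classify_trio(
    matrix: TrioCountMatrix,
    alpha: float = 0.05,
    lfc: float = 1.0,
    mode: str = "mirna",
) -> pd.DataFrame:
    """Full per-feature expression call for a normalized trio matrix.

    Runs the hybrid-vs-MPV additivity test plus the three pairwise tests
    and combines them into a category per feature.  ``mode`` selects the
    pairwise significance rule: ``"mirna"`` uses p < alpha, ``"gene"``
    additionally requires q < alpha.
    """
    if mode not in ("mirna", "gene"):
        raise ValueError(f"mode must be 'mirna' or 'gene', got {mode!r}")
    require_q = mode == "gene"
    calls = classify_additivity(matrix, alpha=alpha, lfc=lfc)
    pw = {
        name: pairwise_test(matrix, a, b, alpha=alpha, lfc=lfc, require_q=require_q)
        for name, (a, b) in COMPARISONS.items()
    }
    categories = [
        classify_pattern(
            calls.loc[f, "additivity"] == "non-additive",
            pw["H_vs_P1"].loc[f],
            pw["H_vs_P2"].loc[f],
            pw["P1_vs_P2"].loc[f],
        )
        for f in matrix.feature_ids
    ]
    calls = calls.copy()
    calls["category"] = categories
    return calls


# ---------------------------------------------------------------------------
# Venn / FPU set logic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VennDecomposition:
    """Region sizes of the three differential-expression sets.

    A = DE(hybrid vs parent 1), B = DE(hybrid vs parent 2),
    C = DE(parent 1 vs parent 2).  The FPU set — features differential
    against a parent but not between the parents — is (A u B) \\ C, i.e.
    the A-only, B-only and (A n B) \\ C regions.
    """

    a_only: int
    b_only: int
    c_only: int
    ab_not_c: int
    ac_not_b: int
    bc_not_a: int
    abc: int
    fpu_members: frozenset

    @property
    def fpu_size(self) -> int:
        return self.a_only + self.b_only + self.ab_not_c

    def regions(self) -> dict[str, int]:
        return {
            "A_only": self.a_only,
            "B_only": self.b_only,
            "C_only": self.c_only,
            "AB_not_C": self.ab_not_c,
            "AC_not_B": self.ac_not_b,
            "BC_not_A": self.bc_not_a,
            "ABC": self.abc,
            "FPU": self.fpu_size,
        }


def venn_fpu(set_a, set_b, set_c) -> VennDecomposition:
    """Three-set Venn decomposition with the parent-unique (FPU) total."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    return VennDecomposition(
        a_only=len(a - b - c),
        b_only=len(b - a - c),
        c_only=len(c - a - b),
        ab_not_c=len((a & b) - c),
        ac_not_b=len((a & c) - b),
        bc_not_a=len((b & c) - a),
        abc=len(a & b & c),
        fpu_members=frozenset((a | b) - c),
    )


def percent_reduction(value: float, reference: float) -> float:
    """Percent decrease of ``value`` relative to ``reference``, 2 decimals."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    if value < 0:
        raise ValueError("value must be non-negative")
    return round(100.0 * (reference - value) / reference, 2)
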