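"""One-way ANOVA, pooled SEM and Duncan's multiple range test.

The experimental design is a balanced completely randomized design with
triplicate measurements per treatment group.  Group means are compared with
Duncan's step-down multiple range test: ranked means spanning p positions
differ when their gap exceeds the least significant range

    LSR_p = q(γ_p, p, df_error) · sqrt(MSE / n),   γ_p = (1 − α)^(p−1)

where q(γ, p, df) is the studentized-range quantile at cumulative
probability γ (Duncan's protected significance level α_p = 1 − (1−α)^(p−1)),
MSE the ANOVA error mean square and n the common group size.  A span is
declared non-significant outright if any enclosing span was non-significant
(the step-down protection rule).  Results carry a compact letter display:
groups sharing a letter are not significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

__all__ = [
    "GroupedMeasurements",
    "AnovaResult",
    "DuncanResult",
    "anova_oneway",
    "duncan_mrt",
    "pooled_sem",
]


@dataclass
class GroupedMeasurements:
    """Ordered (label, replicate values) groups feeding ANOVA/Duncan."""

    groups: list
    alpha: float = 0.05

    def __post_init__(self):
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        clean = []
        for label, values in self.groups:
            arr = np.asarray(values, dtype=float).ravel()
            if arr.size < 2:
                raise ValueError(f"group {label!r} has fewer than 2 replicates")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"group {label!r} has non-finite values")
            clean.append((str(label), arr))
        self.groups = clean
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, group_col: str, value_col: str, alpha: float = 0.05
    ) -> "GroupedMeasurements":
        groups = [
            (label, sub[value_col].to_numpy())
            for label, sub in df.groupby(group_col, sort=False)
        ]
        return cls(groups, alpha=alpha)

    @property
    def labels(self) -> list:
        return [label for label, _ in self.groups]

    @property
    def balanced_n(self) -> int:
        ns = {arr.size for _, arr in self.groups}
        if len(ns) != 1:
            raise ValueError("groups are unbalanced")
        return ns.pop()


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    mse: float
    df_between: int
    df_error: int
    degenerate: bool = False  # MSE == 0: replicates are exact constants


def anova_oneway(data: GroupedMeasurements) -> AnovaResult:
    """Fixed-effects one-way ANOVA from the sums-of-squares decomposition."""
    values = [arr for _, arr in data.groups]
    k = len(values)
    n_total = sum(arr.size for arr in values)
    grand = np.concatenate(values).mean()
    ss_between = sum(arr.size * (arr.mean() - grand) ** 2 for arr in values)
    ss_error = sum(float(np.sum((arr - arr.mean()) ** 2)) for arr in values)
    df_between = k - 1
    df_error = n_total - k
    msb = ss_between / df_between
    mse = ss_error / df_error
    if mse == 0.0:
        # all replicates identical within groups; F is unbounded when means differ
        f_stat = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
        return AnovaResult(f_stat, p, 0.0, df_between, df_error, degenerate=True)
    f_stat = msb / mse
    p = float(f_dist.sf(f_stat, df_between, df_error))
    return AnovaResult(float(f_stat), p, float(mse), df_between, df_error)


def pooled_sem(data: GroupedMeasurements) -> float:
    """Pooled standard error of a group mean, sqrt(MSE / n)."""
    n = data.balanced_n
    return float(np.sqrt(anova_oneway(data).mse / n))


@dataclass
class DuncanResult:
    """Duncan's test output: means, pooled error, letters, pairwise decisions."""

    group_means: dict
    mse: float
    df_error: int
    sem: float
    letters: dict
    pairwise: pd.DataFrame
    alpha: float
    lsr: dict = field(default_factory=dict)

    def summary(self) -> str:
        rows = [
            f"{label:>20s}  {mean:12.6g}  {self.letters[label]}"
            for label, mean in sorted(
                self.group_means.items(), key=lambda kv: -kv[1]
            )
        ]
        return "\n".join(
            [
                f"Duncan's multiple range test (alpha = {self.alpha})",
                f"  MSE = {self.mse:.6g}, df_error = {self.df_error}, "
                f"SEM = {self.sem:.6g}",
                f"{'group':>20s}  {'mean':>12s}  letters",
                *rows,
                "groups sharing a letter are not significantly different",
            ]
        )


def _duncan_nonsig_matrix(
    means_desc: np.ndarray, mse: float, n: int, df_error: int, alpha: float
) -> tuple[np.ndarray, dict]:
    """Boolean k×k matrix (ranked order): True where the pair is NOT significant."""
    k = means_desc.size
    nonsig = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(nonsig, True)
    if mse == 0.0:
        # degenerate: decisions reduce to exact equality of means
        for i in range(k):
            for j in range(i + 1, k):
                eq = means_desc[i] == means_desc[j]
                nonsig[i, j] = nonsig[j, i] = eq
        return nonsig, {}
    se = np.sqrt(mse / n)
    lsr = {
        p: float(studentized_range.ppf((1.0 - alpha) ** (p - 1), p, df_error)) * se
        for p in range(2, k + 1)
    }
    # step-down: widest spans first; a span inside a non-significant span is ns
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            gap = means_desc[i] - means_desc[j]
            enclosed_ns = any(
                nonsig[a, b]
                for a in range(0, i + 1)
                for b in range(j, k)
                if (a, b) != (i, j) and (b - a + 1) > span
            )
            ns = gap <= lsr[span] or enclosed_ns
            nonsig[i, j] = nonsig[j, i] = ns
    return nonsig, lsr


def _letters_from_nonsig(labels_desc, nonsig: np.ndarray) -> dict:
    """Compact letter display by the insert-and-absorb construction.

    Under the step-down rule non-significance is interval-shaped in ranked
    order, so maximal non-significant runs of consecutive ranked means give
    the letter groups directly.
    """
    k = len(labels_desc)
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        intervals.append((i, j))
    # absorb intervals contained in an earlier one
    maximal = []
    for iv in intervals:
        if not any(a <= iv[0] and iv[1] <= b for a, b in maximal):
            maximal.append(iv)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {label: "" for label in labels_desc}
    for idx, (a, b) in enumerate(maximal):
        ch = alphabet[idx % len(alphabet)]
        for i in range(a, b + 1):
            letters[labels_desc[i]] += ch
    return letters


def duncan_mrt(data: GroupedMeasurements, alpha: float | None = None) -> DuncanResult:
    """Duncan's multiple range test with compact letter display.

    Requires balanced groups (the completely randomized triplicate design).
    """
    alpha = data.alpha if alpha is None else alpha
    n = data.balanced_n
    aov = anova_oneway(data)
    means = {label: float(arr.mean()) for label, arr in data.groups}
    order = sorted(means, key=lambda label: -means[label])
    means_desc = np.array([means[label] for label in order])
    nonsig, lsr = _duncan_nonsig_matrix(means_desc, aov.mse, n, aov.df_error, alpha)
    letters = _letters_from_nonsig(order, nonsig)
    pairwise = pd.DataFrame(~nonsig, index=order, columns=order)
    sem = float(np.sqrt(aov.mse / n))
    return DuncanResult(
        group_means=means,
        mse=aov.mse,
        df_error=aov.df_error,
        sem=sem,
        letters={label: letters[label] for label in data.labels},
        pairwise=pairwise,
        alpha=alpha,
        lsr=lsr,
    )
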