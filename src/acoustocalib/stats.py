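"""Group-comparison statistics for slopes, moduli and viability.

One-way ANOVA with the Scheffé all-pairs post hoc is used to compare
deformability slopes and interpolated moduli across cell lines; a
two-tailed two-sample t-test on calcein-AM fluorescence (before vs after
trapping) checks viability at the 1% level.

The ANOVA decomposition and the Scheffé statistic are computed from the
classical sums-of-squares formulas so that the mean squared error and group
means feeding the post hoc are exactly the omnibus quantities.  For a pair
(i, j),

    F_ij = (ȳ_i − ȳ_j)² / (MSE (1/n_i + 1/n_j)),   p = P{F(k−1, N−k) ≥ F_ij/(k−1)}

which is never more liberal than the omnibus test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "AnovaResult",
    "ScheffePair",
    "ViabilityResult",
    "one_way_anova",
    "scheffe_posthoc",
    "viability_test",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    group_labels: tuple[str, ...]
    group_means: tuple[float, ...]
    group_sizes: tuple[int, ...]
    mse: float
    ss_between: float
    ss_within: float


@dataclass(frozen=True)
class ScheffePair:
    labels: tuple[str, str]
    mean_diff: float
    F_scheffe: float
    p_value: float
    significant: bool
    alpha: float = 0.05


@dataclass(frozen=True)
class ViabilityResult:
    normalized_mean: float
    normalized_sd: float
    t: float
    p_value: float
    alpha: float = 0.01

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(out) < 2:
        raise ValidationError("ANOVA needs >=2 groups")
    for label, x in out.items():
        if x.ndim != 1 or x.size < 2:
            raise ValidationError(f"group {label!r} needs >=2 values")
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA from the sums of squares."""
    g = _as_groups(groups)
    labels = tuple(g)
    sizes = np.array([g[label].size for label in labels])
    means = np.array([g[label].mean() for label in labels])
    all_values = np.concatenate([g[label] for label in labels])
    grand = all_values.mean()
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g[label] - m) ** 2) for label, m in zip(labels, means)))
    k = len(labels)
    N = int(sizes.sum())
    df_b, df_w = k - 1, N - k
    if ss_within == 0.0 and ss_between == 0.0:
        raise ValidationError("all values identical: ANOVA undefined")
    mse = ss_within / df_w
    if mse == 0.0:
        F = np.inf
        p = 0.0
    else:
        F = (ss_between / df_b) / mse
        p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        group_labels=labels,
        group_means=tuple(float(m) for m in means),
        group_sizes=tuple(int(n) for n in sizes),
        mse=float(mse),
        ss_between=ss_between,
        ss_within=ss_within,
    )


def scheffe_posthoc(
    groups: Mapping[str, Sequence[float]],
    anova: AnovaResult,
    alpha: float = 0.05,
) -> list[ScheffePair]:
    """Scheffé all-pairwise comparisons using the omnibus MSE.

    Supports unequal group sizes.  ``anova`` must come from the same groups
    (labels and sizes are checked).
    """
    g = _as_groups(groups)
    if tuple(g) != anova.group_labels or tuple(
        x.size for x in g.values()
    ) != anova.group_sizes:
        raise ValidationError("groups do not match the supplied ANOVA result")
    k = len(g)
    pairs: list[ScheffePair] = []
    for (la, xa), (lb, xb) in combinations(g.items(), 2):
        diff = float(xa.mean() - xb.mean())
        denom = anova.mse * (1.0 / xa.size + 1.0 / xb.size)
        if denom == 0.0:
            F_pair = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            F_pair = diff**2 / denom
            p = float(sps.f.sf(F_pair / (k - 1), anova.df_between, anova.df_within))
        pairs.append(
            ScheffePair(
                labels=(la, lb),
                mean_diff=diff,
                F_scheffe=float(F_pair),
                p_value=p,
                significant=p < alpha,
                alpha=alpha,
            )
        )
    return pairs


def viability_test(
    before: Sequence[float],
    after: Sequence[float],
    alpha: float = 0.01,
    welch: bool = False,
) -> ViabilityResult:
    """Before/after fluorescence comparison for trap-induced damage.

    Fluorescence after trapping is normalized by the pre-trap mean so the
    reported mean sits near 1 for unharmed cells.  The test itself is a
    two-tailed two-sample t-test of the raw after vs before values
    (pooled-variance Student's by default; Welch by flag).
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size < 2 or a.size < 2:
        raise ValidationError("viability test needs >=2 values in each arm")
    mb = b.mean()
    if mb <= 0:
        raise ValidationError("non-positive pre-trap mean fluorescence")
    norm = a / mb
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return ViabilityResult(
        normalized_mean=float(norm.mean()),
        normalized_sd=float(np.std(norm, ddof=1)) if norm.size > 1 else 0.0,
        t=float(t),
        p_value=float(p),
        alpha=alpha,
    )
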