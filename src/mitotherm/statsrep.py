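"""Replicate-level statistics and the absolute-temperature reconstruction rule.

Group comparisons follow the study's reporting conventions: means ± sample
SD, one-way ANOVA with Tukey HSD post-hoc pairwise tests for three or more
groups, two-sided unpaired Student's t test for two groups, and significance
stars at 0.05 / 0.01 / 0.001.

The headline absolute temperature is reconstructed additively: if inhibiting
ATP synthase abolishes all mitochondrial heat production, the pre-inhibition
mitochondrial temperature is the ambient temperature plus the measured
decrease magnitude — a lower bound whenever residual heat production
remains.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "group_summary",
    "compare_groups",
    "significance_stars",
    "reconstruct_mito_temperature",
]


def significance_stars(p: float) -> str:
    """Figure-legend stars: * < 0.05, ** < 0.01, *** < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_summary(values) -> tuple[float, float | None]:
    """Mean and sample SD (n−1); SD is None for a single replicate."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    sd = float(v.std(ddof=1)) if v.size > 1 else None
    return float(v.mean()), sd


@dataclass
class GroupComparison:
    """One-way comparison of labelled replicate groups."""

    labels: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    anova_f: float
    anova_p: float
    tukey_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    ttest_t: float | None = None
    ttest_p: float | None = None
    alpha: float = 0.05

    def stars(self, pair: tuple[str, str] | None = None) -> str:
        if pair is not None:
            key = pair if pair in self.tukey_pairs else (pair[1], pair[0])
            return significance_stars(self.tukey_pairs[key])
        p = self.ttest_p if self.ttest_p is not None else self.anova_p
        return significance_stars(p)

    def summary(self) -> str:
        lines = ["group comparison", "=" * 46]
        for lab in self.labels:
            lines.append(f"{lab:>16}: {self.means[lab]:8.3f} ± {self.sds[lab]:.3f} °C")
        lines.append(f"one-way ANOVA: F = {self.anova_f:.4f}, p = {self.anova_p:.4g} "
                     f"{significance_stars(self.anova_p)}")
        if self.ttest_p is not None:
            lines.append(f"Student's t:   t = {self.ttest_t:.4f}, p = {self.ttest_p:.4g} "
                         f"{significance_stars(self.ttest_p)}")
        for (a, b), p in self.tukey_pairs.items():
            lines.append(f"Tukey {a} vs {b}: p = {p:.4g} {significance_stars(p)}")
        return "\n".join(lines)


def compare_groups(groups: dict[str, list[float]], alpha: float = 0.05,
                   welch: bool = False) -> GroupComparison:
    """One-way ANOVA (+ Tukey HSD for ≥ 3 groups, t test for 2 groups).

    ``groups`` maps label → per-replicate values (each n ≥ 2). The t test is
    unpaired and equal-variance by default ("Student's t"); pass
    ``welch=True`` for the unequal-variance form. Tukey HSD adjusted p
    values use the studentized-range distribution.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    for lab, arr in zip(labels, arrays):
        if arr.size < 2:
            raise ValueError(f"group {lab!r} has n < 2")
    means = {lab: float(a.mean()) for lab, a in zip(labels, arrays)}
    sds = {lab: float(a.std(ddof=1)) for lab, a in zip(labels, arrays)}

    pooled = np.concatenate(arrays)
    degenerate = np.allclose(pooled, pooled[0])
    if degenerate:
        # every observation identical: define F = 0, p = 1 rather than 0/0
        f_stat, f_p = 0.0, 1.0
    else:
        f_stat, f_p = stats.f_oneway(*arrays)
        f_stat, f_p = float(f_stat), float(f_p)

    t_stat = t_p = None
    tukey: dict[tuple[str, str], float] = {}
    if len(labels) == 2:
        if degenerate:
            t_stat, t_p = 0.0, 1.0
        else:
            res = stats.ttest_ind(arrays[0], arrays[1], equal_var=not welch)
            t_stat, t_p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.tukey_hsd(*arrays)
        for i, j in itertools.combinations(range(len(labels)), 2):
            tukey[(labels[i], labels[j])] = float(res.pvalue[i, j])

    return GroupComparison(
        labels=labels, means=means, sds=sds,
        anova_f=f_stat, anova_p=f_p, tukey_pairs=tukey,
        ttest_t=t_stat, ttest_p=t_p, alpha=alpha,
    )


def reconstruct_mito_temperature(ambient: float, decrease_magnitude: float) -> float:
    """Pre-inhibition mitochondrial temperature from ambient + measured drop.

    Assumes full inhibition abolishes all mitochondrial heat production, so
    the post-inhibition probe reading sits at ambient; the returned value is
    a lower bound whenever residual heat production remains.
    """
    if decrease_magnitude < 0:
        raise ValueError("decrease magnitude must be non-negative")
    return float(ambient) + float(decrease_magnitude)
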