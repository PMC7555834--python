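"""Group comparison of strain-stability pattern frequencies.

The question: do exposure groups (e.g. antibiotics vs none) differ in how
often subjects exhibit a given stability pattern?  The response is a
per-subject binary indicator of pattern presence (one row per subject x
pattern class, which avoids pseudo-replication across species; a
per-species-occurrence unit is available via ``unit``).  Groups are
compared by one-way ANOVA followed by Tukey's HSD post-hoc test.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datatypes import Pattern, SampleMeta, StabilityPattern

__all__ = ["GroupComparison", "compare_groups", "pattern_indicator_table"]


@dataclass
class GroupComparison:
    """One-way ANOVA + Tukey HSD over exposure groups for one response."""

    f_stat: float
    p_value: float
    group_means: Dict[str, float]
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject
    degenerate: bool  # zero within-group variance everywhere -> no p-value

    def summary(self) -> str:
        lines = [
            f"one-way ANOVA: F = {self.f_stat:.4g}, p = {self.p_value:.4g}"
            + ("  [degenerate: no within-group variance]" if self.degenerate else ""),
            "group means: "
            + ", ".join(f"{g}={m:.3g}" for g, m in sorted(self.group_means.items())),
            self.tukey.to_string(index=False),
        ]
        return "\n".join(lines)


def compare_groups(values_by_group: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Compare per-subject responses across >= 2 groups (>= 2 subjects each).

    Returns the ANOVA F and p plus Tukey-adjusted pairwise p-values.  When
    every group has zero within-group variance the F statistic is
    undefined; the result is flagged degenerate and carries NaN p-values.
    """
    groups = sorted(values_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {g: np.asarray(values_by_group[g], dtype=float) for g in groups}
    for g, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    means = {g: float(arr.mean()) for g, arr in arrays.items()}
    degenerate = all(np.ptp(arr) == 0 for arr in arrays.values())

    if degenerate:
        f_stat, p_value = float("nan"), float("nan")
        rows = []
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1 :]:
                rows.append((g1, g2, means[g2] - means[g1], float("nan"), False))
        tukey_df = pd.DataFrame(rows, columns=["group1", "group2", "meandiff", "p_adj", "reject"])
        return GroupComparison(f_stat, p_value, means, tukey_df, True)

    f_stat, p_value = sps.f_oneway(*(arrays[g] for g in groups))
    values = np.concatenate([arrays[g] for g in groups])
    labels = np.concatenate([[g] * len(arrays[g]) for g in groups])
    tk = pairwise_tukeyhsd(values, labels)
    uniq = [str(g) for g in tk.groupsunique]
    pairs = [(uniq[i], uniq[j]) for i in range(len(uniq)) for j in range(i + 1, len(uniq))]
    tukey_df = pd.DataFrame(
        {
            "group1": [p[0] for p in pairs],
            "group2": [p[1] for p in pairs],
            "meandiff": np.asarray(tk.meandiffs, dtype=float),
            "p_adj": np.asarray(tk.pvalues, dtype=float),
            "reject": np.asarray(tk.reject, dtype=bool),
        }
    )
    return GroupComparison(float(f_stat), float(p_value), means, tukey_df, False)


def pattern_indicator_table(
    patterns: Sequence[StabilityPattern],
    meta: Sequence[SampleMeta],
    unit: str = "subject",
) -> pd.DataFrame:
    """Binary pattern-presence indicators per analysis unit.

    ``unit='subject'`` (default): one row per subject x pattern class,
    indicator 1 when any species of that subject shows the pattern.
    ``unit='species'``: one row per subject x species x pattern class.
    Columns: subject_id, group, pattern, indicator (plus species_id for the
    species unit).
    """
    if unit not in ("subject", "species"):
        raise ValueError("unit must be 'subject' or 'species'")
    group_of = {}
    for m in meta:
        group_of[m.subject_id] = "antibiotics" if m.antibiotic_exposed else "no_antibiotics"
    subjects = sorted({p.subject_id for p in patterns})
    rows = []
    if unit == "subject":
        for subj in subjects:
            observed = {p.pattern for p in patterns if p.subject_id == subj}
            for cls in Pattern:
                rows.append(
                    {
                        "subject_id": subj,
                        "group": group_of.get(subj, "no_antibiotics"),
                        "pattern": cls.value,
                        "indicator": int(cls in observed),
                    }
                )
        return pd.DataFrame(rows, columns=["subject_id", "group", "pattern", "indicator"])
    for p in sorted(patterns, key=lambda p: (p.subject_id, p.species_id)):
        for cls in Pattern:
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "species_id": p.species_id,
                    "group": group_of.get(p.subject_id, "no_antibiotics"),
                    "pattern": cls.value,
                    "indicator": int(p.pattern == cls),
                }
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "species_id", "group", "pattern", "indicator"]
    )
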