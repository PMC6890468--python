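"""Treatment-comparison statistics.

The incubation endpoints are small-n and generally non-normal, so the
battery is: Shapiro-Wilk normality per group, a tie-corrected
Kruskal-Wallis omnibus, pairwise Wilcoxon rank-sum tests with
Benjamini-Hochberg FDR adjustment, and a compact letter display in which
groups sharing a letter are not significantly different.  Individual tests
are backed by scipy/statsmodels; the letter display is constructed here by
the insert-and-absorb algorithm.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["TestReport", "compare_treatments", "paired_signed_rank", "linear_fit"]

#: Below this per-group size the rank-sum test uses the exact null
#: distribution; at or above it, the normal approximation.
EXACT_SIZE_THRESHOLD = 25


@dataclass
class TestReport:
    """Omnibus + post-hoc results for one response variable."""

    test_name: str
    statistic: float
    df: int
    p_value: float
    group_sizes: dict = field(default_factory=dict)
    shapiro_p: dict = field(default_factory=dict)
    pairwise: pd.DataFrame | None = None
    letters: dict = field(default_factory=dict)
    degenerate: bool = False

    def to_text(self) -> str:
        if self.degenerate:
            return f"{self.test_name}: undefined statistic (all observations tied)"
        lines = [
            f"{self.test_name} chi2({self.df})={self.statistic:.4g}, p={self.p_value:.4g}"
        ]
        if self.letters:
            disp = ", ".join(f"{g}: {l}" for g, l in self.letters.items())
            lines.append(f"letters: {disp}")
        if self.pairwise is not None and len(self.pairwise):
            lines.append(self.pairwise.to_string(index=False))
        return "\n".join(lines)


def _letters_from_pairs(groups, nonsig_pairs) -> dict:
    """Compact letter display by insertion and absorption.

    Starts from one letter-set per group and merges sets so that every
    non-significant pair shares a letter and no significant pair does.
    """
    sets: list[set] = [{g} for g in groups]
    for a, b in nonsig_pairs:
        if any(a in s and b in s for s in sets):
            continue
        merged = False
        for s in sets:
            if a in s or b in s:
                cand = s | {a, b}
                # only merge if cand introduces no significant pair
                ok = all(
                    (x, y) in nonsig_pairs or (y, x) in nonsig_pairs or x == y
                    for x, y in itertools.combinations(sorted(cand), 2)
                )
                if ok:
                    s |= {a, b}
                    merged = True
                    break
        if not merged:
            sets.append({a, b})
    # absorb subsets
    sets = [s for s in sets if not any(s < t for t in sets)]
    sets.sort(key=lambda s: min(groups.index(g) for g in s))
    letters = {g: "" for g in groups}
    for s, letter in zip(sets, "abcdefghijklmnopqrstuvwxyz"):
        for g in groups:
            if g in s:
                letters[g] += letter
    return letters


def compare_treatments(
    df: pd.DataFrame, value_col: str, group_col: str = "treatment",
    alpha: float = 0.05,
) -> TestReport:
    """Kruskal-Wallis omnibus with BH-adjusted pairwise rank-sum post-hocs.

    Requires >= 2 groups with >= 2 non-missing observations each.  All-tied
    data yields a report flagged ``degenerate`` with NaN statistics rather
    than an exception.
    """
    clean = df[[group_col, value_col]].dropna()
    groups = list(dict.fromkeys(clean[group_col]))
    samples = {g: clean.loc[clean[group_col] == g, value_col].to_numpy(dtype=float)
               for g in groups}
    if len(groups) < 2 or any(len(v) < 2 for v in samples.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    sizes = {g: len(v) for g, v in samples.items()}
    pooled = np.concatenate(list(samples.values()))
    if np.ptp(pooled) == 0:
        return TestReport("Kruskal-Wallis", math.nan, len(groups) - 1, math.nan,
                          group_sizes=sizes, degenerate=True)
    shapiro_p = {}
    for g, v in samples.items():
        shapiro_p[g] = float(sps.shapiro(v).pvalue) if np.ptp(v) > 0 and len(v) >= 3 else math.nan
    kw = sps.kruskal(*samples.values())  # tie-corrected by default
    rows = []
    for a, b in itertools.combinations(groups, 2):
        x, y = samples[a], samples[b]
        method = ("exact" if max(len(x), len(y)) < EXACT_SIZE_THRESHOLD
                  and np.ptp(np.concatenate([x, y])) > 0 else "asymptotic")
        try:
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        except ValueError:  # exact method refuses ties
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        rows.append({"group_a": a, "group_b": b, "U": float(res.statistic),
                     "p_raw": float(res.pvalue)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = multipletests(pairwise["p_raw"], method="fdr_bh")[1]
    nonsig = {(r.group_a, r.group_b) for r in pairwise.itertuples()
              if r.p_adj >= alpha}
    nonsig |= {(b, a) for a, b in nonsig}
    letters = _letters_from_pairs(groups, nonsig)
    return TestReport(
        "Kruskal-Wallis", float(kw.statistic), len(groups) - 1, float(kw.pvalue),
        group_sizes=sizes, shapiro_p=shapiro_p, pairwise=pairwise, letters=letters,
    )


def paired_signed_rank(x, y) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired designs (e.g. vs the T0h state)."""
    res = sps.wilcoxon(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def linear_fit(x, y) -> tuple[float, float, float, float]:
    """OLS line fit: (slope, intercept, R^2, slope-test p value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    res = sps.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue**2), float(res.pvalue))
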