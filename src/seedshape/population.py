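"""Population-level summaries and nonparametric group comparisons.

Per-group trait summaries report mean, SD, min, max and the coefficient
of variation ``CV = SD / mean * 100``.  Group comparisons use the
Kruskal–Wallis omnibus test (three or more groups; a two-sample
Wilcoxon–Mann–Whitney rank test for two), followed by pairwise rank-sum
tests with Holm correction and a greedy compact-letter display: groups
sharing a letter do not differ significantly at the chosen alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_TRAITS = ("A", "P", "L", "W", "AR", "C", "R")


@dataclass(frozen=True)
class GroupComparison:
    trait: str
    statistic: float  # Kruskal-Wallis H (or Mann-Whitney U for 2 groups)
    p_value: float
    letters: Dict[str, str]  # group -> letter codes, e.g. "ab"
    alpha: float
    pairwise_p: Optional[pd.DataFrame] = None


def summarize(
    table: pd.DataFrame,
    group_key: str,
    traits: Sequence[str] = DEFAULT_TRAITS,
) -> pd.DataFrame:
    """Per-group mean, sd, min, max and CV for each trait.

    Single-valued groups report sd = 0; a zero-mean trait leaves CV
    missing (NaN) with a warning.
    """
    traits = [t for t in traits if t in table.columns]
    if group_key not in table.columns:
        raise KeyError(f"column {group_key!r} not in table")
    if not traits:
        raise ValueError("no trait columns found in table")
    rows = []
    for group, sub in table.groupby(group_key, sort=True):
        row: dict = {group_key: group, "n": len(sub)}
        for t in traits:
            vals = sub[t].to_numpy(dtype=float)
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            row[f"{t}_mean"] = mean
            row[f"{t}_sd"] = sd
            row[f"{t}_min"] = float(np.min(vals))
            row[f"{t}_max"] = float(np.max(vals))
            if mean == 0.0:
                warnings.warn(
                    f"CV undefined for trait {t!r} in group {group!r} "
                    "(zero mean)", stacklevel=2)
                row[f"{t}_cv"] = np.nan
            else:
                row[f"{t}_cv"] = cv_percent(mean, sd)
        rows.append(row)
    return pd.DataFrame(rows).set_index(group_key)


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation: sd / mean * 100."""
    return sd / mean * 100.0


def _greedy_letters(
    groups: List[str], sig: Dict[frozenset, bool]
) -> Dict[str, str]:
    """Greedy compact-letter display: groups sharing a letter are pairwise
    non-significant.  ``groups`` should be ordered (e.g. by median)."""
    sets: List[set] = []
    for g in groups:
        placed = False
        for s in sets:
            if g in s:
                placed = True
                continue
            if all(not sig[frozenset((g, h))] for h in s):
                s.add(g)
                placed = True
        if not placed:
            newset = {g}
            for h in groups:
                if h == g or h in newset:
                    continue
                if not sig[frozenset((g, h))] and all(
                        not sig[frozenset((h, m))] for m in newset):
                    newset.add(h)
            sets.append(newset)
    # drop letter sets wholly contained in another
    sets = [s for i, s in enumerate(sets)
            if not any(s < t for j, t in enumerate(sets) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in s:
            out[g] += letter
    for g in out:  # safety: every group carries at least one letter
        if not out[g]:
            out[g] = alphabet[len(sets)]
    return out


def compare_groups(
    table: pd.DataFrame,
    trait: str,
    group_key: str,
    alpha: float = 0.05,
) -> GroupComparison:
    """Nonparametric comparison of a trait across groups.

    Three or more groups: Kruskal–Wallis omnibus + Holm-corrected
    pairwise Mann–Whitney tests feeding a compact-letter display.  Two
    groups: two-sided Mann–Whitney, letters {a, b} iff p < alpha.
    """
    samples = {
        str(g): sub[trait].to_numpy(dtype=float)
        for g, sub in table.groupby(group_key, sort=True)
    }
    names = sorted(samples, key=lambda g: np.median(samples[g]))
    if len(names) < 2:
        raise ValueError("need at least 2 groups to compare")
    if len(names) == 2:
        u, p = stats.mannwhitneyu(samples[names[0]], samples[names[1]],
                                  alternative="two-sided")
        letters = ({names[0]: "a", names[1]: "b"} if p < alpha
                   else {names[0]: "a", names[1]: "a"})
        return GroupComparison(trait=trait, statistic=float(u),
                               p_value=float(p), letters=letters, alpha=alpha)
    h, p = stats.kruskal(*(samples[g] for g in names))
    pairs = [(names[i], names[j]) for i in range(len(names))
             for j in range(i + 1, len(names))]
    raw = [
        stats.mannwhitneyu(samples[a], samples[b],
                           alternative="two-sided").pvalue
        for a, b in pairs
    ]
    adj = multipletests(raw, alpha=alpha, method="holm")[1]
    sig = {frozenset(pair): bool(q < alpha) for pair, q in zip(pairs, adj)}
    pw = pd.DataFrame(
        [{"group_a": a, "group_b": b, "p_raw": r, "p_holm": q}
         for (a, b), r, q in zip(pairs, raw, adj)]
    )
    letters = _greedy_letters(names, sig)
    return GroupComparison(trait=trait, statistic=float(h), p_value=float(p),
                           letters=letters, alpha=alpha, pairwise_p=pw)


def model_affinity_matrix(
    j_table: pd.DataFrame,
    group_key: str = "species",
    model_key: str = "model",
    value_key: str = "J",
) -> pd.DataFrame:
    """Group x model matrix of mean J, rows/columns sorted; absent
    (group, model) cells are NaN."""
    if j_table.empty:
        raise ValueError("empty J table")
    mat = j_table.pivot_table(index=group_key, columns=model_key,
                              values=value_key, aggfunc="mean")
    return mat.sort_index(axis=0).sort_index(axis=1)
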