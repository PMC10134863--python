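"""Group comparison of genome traits across genera.

Genera are independent groups of genomes, so trait differences are tested
with the unpaired two-sample Wilcoxon rank-sum (Mann–Whitney U) test per
group pair, Benjamini–Hochberg adjusted across pairs.  A compact letter
display summarises the result: groups that are *not* significantly
different at the configured alpha share at least one letter.
"""

from __future__ import annotations

import itertools
import string
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = ["group_compare", "compact_letters"]


def group_compare(trait_table: pd.DataFrame, group_map: Mapping[str, str],
                  trait: str, alpha: float = 0.005,
                  adjust: bool = True) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pairwise rank-sum tests of one trait between groups of genomes.

    ``trait_table`` must carry a ``genome_id`` column and the trait column;
    ``group_map`` assigns genomes to groups.  Singleton groups are dropped
    with a warning.  Returns the pairwise test table (with BH-adjusted
    p-values when ``adjust``) and the letter assignment per group.
    """
    if trait not in trait_table.columns:
        raise KeyError(f"trait column {trait!r} not in table")
    values: dict[str, np.ndarray] = {}
    for group in sorted(set(group_map.values())):
        members = [g for g, grp in group_map.items() if grp == group]
        vals = trait_table.loc[
            trait_table["genome_id"].isin(members), trait
        ].dropna().to_numpy()
        if vals.size < 2:
            warnings.warn(f"group {group!r} has <2 members; excluded")
            continue
        values[group] = vals
    if len(values) < 2:
        raise ValueError("need at least two groups with ≥2 members")

    rows = []
    for a, b in itertools.combinations(sorted(values), 2):
        stat, p = mannwhitneyu(values[a], values[b], alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "statistic": float(stat),
                     "p_value": float(p)})
    table = pd.DataFrame(rows)
    if adjust:
        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["p_adjusted"] = table["p_value"]

    not_different = {
        (r.group_a, r.group_b)
        for r in table.itertuples(index=False) if r.p_adjusted >= alpha
    }
    medians = {g: float(np.median(v)) for g, v in values.items()}
    letters = compact_letters(sorted(values), not_different, medians)
    return table, letters


def compact_letters(groups: Sequence[str],
                    not_different: set[tuple[str, str]],
                    medians: Mapping[str, float] | None = None) -> dict[str, str]:
    """Greedy compact letter display.

    Two groups share a letter iff they were not significantly different.
    Groups are processed in descending median order (alphabetical fallback)
    so the letters read along the trait gradient.
    """
    same = {g: {g} for g in groups}
    for a, b in not_different:
        same[a].add(b)
        same[b].add(a)
    ordered = sorted(groups, key=lambda g: (-(medians or {}).get(g, 0.0), g))
    letter_sets: list[set[str]] = []  # groups covered by each letter
    for g in ordered:
        placed = False
        for members in letter_sets:
            if all(other in same[g] for other in members):
                members.add(g)
                placed = True
        covered = any(g in members for members in letter_sets)
        if not placed and not covered:
            letter_sets.append({g})
        elif not covered:
            letter_sets.append({g})
    # ensure every non-different pair shares a letter
    for a, b in not_different:
        if not any(a in s and b in s for s in letter_sets):
            letter_sets.append({a, b})
    out = {g: "" for g in groups}
    for letter, members in zip(string.ascii_lowercase, letter_sets):
        for g in members:
            out[g] += letter
    return out
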