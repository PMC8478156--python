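"""Group-comparison statistics: Fisher/FDR, Kruskal–Wallis and Dunn's test.

Binary alteration features are compared between patient groups with
two-sided Fisher exact tests corrected by Benjamini–Hochberg FDR; continuous
metrics (TMB, CIN) are compared across groups with the Kruskal–Wallis rank
test followed by Dunn's pairwise post hoc z tests with tie correction.
"""
from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .landscape import CohortMatrix

logger = logging.getLogger(__name__)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table ``[[a, b], [c, d]]``.

    Two-sided by summation of hypergeometric table probabilities no larger
    than the observed table's. A table with any zero margin carries no
    information and returns 1.0.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_group_test(
    matrix: CohortMatrix,
    grouping: Mapping[str, str],
    q_cutoff: float = 0.1,
    fdr_family: str = "per_pair",
) -> pd.DataFrame:
    """Fisher tests of every feature between every unordered group pair.

    The FDR family defaults to all tested features within one group pair
    (``fdr_family="global"`` corrects across all pairs jointly). Features
    altered in no patient of a pair are recorded untested and consume no
    FDR slots.
    """
    if fdr_family not in ("per_pair", "global"):
        raise ValueError("fdr_family must be 'per_pair' or 'global'")
    members: dict[str, list[str]] = {}
    for pid in matrix.values.index:
        g = grouping.get(pid)
        if g is not None:
            members.setdefault(g, []).append(pid)
    empty = [g for g, pats in members.items() if not pats]
    for g in empty:
        logger.warning("group %r is empty; dropped", g)
        del members[g]
    if len(members) < 2:
        raise ValueError("need at least two non-empty groups")

    rows = []
    for g1, g2 in combinations(sorted(members), 2):
        idx1, idx2 = members[g1], members[g2]
        n1, n2 = len(idx1), len(idx2)
        sub1 = matrix.values.loc[idx1].sum(axis=0)
        sub2 = matrix.values.loc[idx2].sum(axis=0)
        for feature in matrix.values.columns:
            a, c = int(sub1[feature]), int(sub2[feature])
            b, d = n1 - a, n2 - c
            if a + c == 0:
                rows.append(
                    dict(feature=feature, group1=g1, group2=g2, a=a, b=b, c=c,
                         d=d, direction="none", p_value=np.nan, tested=False)
                )
                continue
            if a / n1 > c / n2:
                direction = "higher_in_group1"
            elif a / n1 < c / n2:
                direction = "higher_in_group2"
            else:
                direction = "equal"
            rows.append(
                dict(feature=feature, group1=g1, group2=g2, a=a, b=b, c=c, d=d,
                     direction=direction, p_value=fisher_exact_2x2(a, b, c, d),
                     tested=True)
            )
    df = pd.DataFrame(rows)
    df["q_value"] = np.nan
    tested = df["tested"]
    if fdr_family == "global":
        if tested.any():
            df.loc[tested, "q_value"] = bh_fdr(df.loc[tested, "p_value"])
    else:
        for _, idx in df[tested].groupby(["group1", "group2"]).groups.items():
            df.loc[idx, "q_value"] = bh_fdr(df.loc[idx, "p_value"])
    df["significant"] = df["q_value"] < q_cutoff
    return df


def kruskal_wallis(
    values: Sequence[float], groups: Sequence[str]
) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-square p across groups."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    samples = [values[labels == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def dunn_posthoc(
    values: Sequence[float],
    groups: Sequence[str],
    adjust: str = "BH",
) -> pd.DataFrame:
    """Dunn's rank-based pairwise post hoc test after Kruskal–Wallis.

    For groups *i*, *j* with mean ranks :math:`\\bar R_i`, the statistic is

    .. math::
        z_{ij} = (\\bar R_i - \\bar R_j) \\Big/
            \\sqrt{\\Big(\\frac{N(N+1)}{12} -
            \\frac{\\sum_t (t^3 - t)}{12(N-1)}\\Big)
            \\Big(\\frac{1}{n_i} + \\frac{1}{n_j}\\Big)}

    with the tie term summed over tied-value groups. Two-sided normal
    p-values are adjusted across all pairs (BH by default, or Bonferroni).
    """
    if adjust not in ("BH", "bonferroni", "none"):
        raise ValueError("adjust must be 'BH', 'bonferroni' or 'none'")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = [g for g in pd.unique(labels)]
    sizes = {g: int((labels == g).sum()) for g in uniq}
    for g in [g for g in uniq if sizes[g] == 0]:
        logger.warning("group %r has no observations; excluded", g)
        uniq.remove(g)
    if len(uniq) < 2:
        raise ValueError("need at least two non-empty groups")
    n_total = len(values)
    ranks = sps.rankdata(values)
    mean_ranks = {g: ranks[labels == g].mean() for g in uniq}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    rows = []
    for g1, g2 in combinations(uniq, 2):
        se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = 0.0 if se == 0 else (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(dict(group1=g1, group2=g2, z=z, p_value=min(p, 1.0)))
    df = pd.DataFrame(rows)
    if adjust == "BH":
        df["p_adjusted"] = bh_fdr(df["p_value"])
    elif adjust == "bonferroni":
        df["p_adjusted"] = np.minimum(df["p_value"] * len(df), 1.0)
    else:
        df["p_adjusted"] = df["p_value"]
    return df


def compare_to_reference(
    our_counts: Mapping[str, tuple[int, int]],
    ref_counts: Mapping[str, tuple[int, int]],
    q_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Per-gene prevalence comparison against an external reference cohort.

    Both arguments map gene -> (n_mutated, n_total). Genes absent from the
    reference are reported untested; Fisher p-values over the shared genes
    are BH-corrected.
    """
    rows = []
    for gene, (a, n1) in our_counts.items():
        if gene not in ref_counts:
            rows.append(dict(gene=gene, our_mut=a, our_total=n1, ref_mut=np.nan,
                             ref_total=np.nan, direction="none",
                             p_value=np.nan, tested=False))
            continue
        c, n2 = ref_counts[gene]
        if a / n1 > c / n2:
            direction = "higher_in_ours"
        elif a / n1 < c / n2:
            direction = "lower_in_ours"
        else:
            direction = "equal"
        rows.append(
            dict(gene=gene, our_mut=a, our_total=n1, ref_mut=c, ref_total=n2,
                 direction=direction,
                 p_value=fisher_exact_2x2(a, n1 - a, c, n2 - c), tested=True)
        )
    df = pd.DataFrame(rows)
    df["q_value"] = np.nan
    if df["tested"].any():
        df.loc[df["tested"], "q_value"] = bh_fdr(df.loc[df["tested"], "p_value"])
    df["significant"] = df["q_value"] < q_cutoff
    return df


def read_reference_counts(path) -> dict[str, tuple[int, int]]:
    """Read a reference frequency TSV (gene, n_mutated, n_total)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "n_mutated", "n_total"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return {
        str(r.gene): (int(r.n_mutated), int(r.n_total)) for r in df.itertuples()
    }
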