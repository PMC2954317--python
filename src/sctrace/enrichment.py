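"""Overrepresentation statistics and miRNA differential expression.

Gene-set overlaps (knockdown response sets, the Oct4 pluripotency network,
miRNA target classes) are tested with an upper-tail hypergeometric test:
given a query set of size n and a category of size K inside a universe of
size N, the p-value is P(overlap >= observed).  Enrichment fold is the
observed overlap rate relative to the category's share of the universe,
(k/n) / (K/N).

miRNA targets are taken as *consensus* predictions: a (miRNA, gene) pair
counts only when at least two of the three prediction algorithms (PicTar,
Miranda, TargetScan) report it, reducing prediction noise.  miRNA
differential expression between cell types is a two-sided Welch t-test on
log2 relative expression across biological replicates (three per type in
the profiling design).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap of a query set with a category within a universe."""

    n_query: int
    n_category: int
    n_universe: int
    overlap: int
    fold: float  #: (overlap/query) / (category/universe); NaN if undefined
    p: float  #: upper-tail hypergeometric P(X >= overlap)


def hypergeom_overlap(query, category, universe) -> EnrichmentResult:
    """Upper-tail hypergeometric overrepresentation test.

    ``query`` and ``category`` must be subsets of ``universe``.  An empty
    query or category yields fold NaN and p = 1.
    """
    query, category, universe = set(query), set(category), set(universe)
    if not query <= universe or not category <= universe:
        raise ValueError("query and category must be subsets of the universe")
    N, K, n = len(universe), len(category), len(query)
    k = len(query & category)
    if n == 0 or K == 0:
        return EnrichmentResult(n, K, N, k, float("nan"), 1.0)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    fold = (k / n) / (K / N)
    return EnrichmentResult(n, K, N, k, fold, min(p, 1.0))


def consensus_targets(
    tables: Iterable[pd.DataFrame] | pd.DataFrame, min_algorithms: int = 2
) -> dict[str, set[str]]:
    """Keep (miRNA, gene) pairs predicted by at least ``min_algorithms``.

    ``tables`` is either a list of per-algorithm DataFrames or one long
    DataFrame; each needs columns (algorithm, mirna, gene).  Duplicate pairs
    within an algorithm count once.
    """
    if isinstance(tables, pd.DataFrame):
        long = tables
    else:
        long = pd.concat(list(tables), ignore_index=True)
    required = {"algorithm", "mirna", "gene"}
    if not required.issubset(long.columns):
        raise ValueError(f"target tables need columns {sorted(required)}")
    dedup = long.drop_duplicates(["algorithm", "mirna", "gene"])
    n_alg = dedup.groupby(["mirna", "gene"])["algorithm"].nunique()
    kept = n_alg[n_alg >= min_algorithms]
    out: dict[str, set[str]] = {}
    for mirna, gene in kept.index:
        out.setdefault(mirna, set()).add(gene)
    return out


def pooled_targets(
    mirnas: Iterable[str], consensus: Mapping[str, set[str]], weighted: bool = False
):
    """Union of the consensus targets of a miRNA set (genes counted once).

    With ``weighted`` the multiset of pairs is returned instead (one entry
    per (miRNA, gene) prediction)."""
    if weighted:
        return [g for m in mirnas for g in sorted(consensus.get(m, set()))]
    out: set[str] = set()
    for m in mirnas:
        out |= consensus.get(m, set())
    return out


def mirna_class_enrichment(
    mirnas: Iterable[str],
    consensus: Mapping[str, set[str]],
    gene_class,
    universe,
) -> EnrichmentResult:
    """Test whether a miRNA set's pooled targets are enriched in a gene class.

    Targets are pooled as a set union across the miRNAs and intersected with
    the universe; the class (e.g. early-differentiation genes selected by
    fold-change and pluripotency-correlation filters) is tested
    hypergeometrically within the same universe, so control classes can be
    tested identically.
    """
    universe = set(universe)
    targets = pooled_targets(mirnas, consensus) & universe
    gene_class = set(gene_class) & universe
    return hypergeom_overlap(targets, gene_class, universe)


def mirna_de(
    profile: pd.DataFrame,
    groups: Mapping[str, Iterable[str]],
    type_a: str,
    type_b: str,
    alpha: float = 0.01,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
) -> pd.DataFrame:
    """Per-miRNA differential expression between two sample types.

    ``profile`` is miRNA x replicate-columns of relative expression;
    ``groups`` maps each sample type to its replicate column names (three
    biological replicates in the profiling design; fewer than two are
    flagged).  The test is a two-sided Welch t-test on log2 expression
    across replicates; fc is the ratio of replicate means (linear scale).
    """
    cols_a, cols_b = list(groups[type_a]), list(groups[type_b])
    flagged = min(len(cols_a), len(cols_b)) < 2
    A = profile[cols_a].to_numpy(dtype=float)
    B = profile[cols_b].to_numpy(dtype=float)
    if (A <= 0).any() or (B <= 0).any():
        floor = np.nanmin(np.concatenate([A[A > 0], B[B > 0]])) if (A > 0).any() else 1e-6
        A = np.maximum(A, floor)
        B = np.maximum(B, floor)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    fc = mean_a / mean_b
    la, lb = np.log2(A), np.log2(B)
    p = np.ones(len(profile))
    for i in range(len(profile)):
        if flagged:
            p[i] = float("nan")
        elif np.ptp(la[i]) == 0 and np.ptp(lb[i]) == 0:
            p[i] = 1.0 if la[i, 0] == lb[i, 0] else 0.0
        else:
            p[i] = float(stats.ttest_ind(la[i], lb[i], equal_var=False).pvalue)
    call = np.full(len(profile), "unchanged", dtype=object)
    call[(fc > fc_hi) & (p < alpha)] = "up"
    call[(fc < fc_lo) & (p < alpha)] = "down"
    out = pd.DataFrame(
        {
            "mirna": profile.index,
            "group_a": type_a,
            "group_b": type_b,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fc": fc,
            "p": p,
            "call": call,
        }
    ).reset_index(drop=True)
    out.attrs["replicates_flagged"] = flagged
    return out
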