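"""Differential expression at gene and transcript-variant level.

Gene-level calls compare single-cell RPM profiles between two cell groups:
fold change is the ratio of group mean RPMs (both floored at the 0.1-RPM
detection pseudo-count) and the p-value comes from a two-sided Welch t-test
on log2(RPM + 1) across cells (Wilcoxon rank-sum available as an
alternative).  A gene is *up* when fc > 4 and p < 0.01, *down* when
fc < 0.25 and p < 0.01 (strict inequalities), *not_expressed* when both
group means sit at or below the floor.

Variant-level calls work on pooled junction counts per sample: a variant is
*expressed* when its discriminating junctions carry at least 5 counts in
either sample; fold change is on the RPM scale with thresholds 2 / 0.5; the
p-value is a two-sided Fisher exact test on (count, library - count); a
variant with zero counts on one side and >= 5 on the other is *gained* /
*lost*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .junction_quant import JunctionCountTable, JunctionReference, fold_change

RPM_FLOOR = 0.1
DE_COLUMNS = ["feature", "level", "group_a", "group_b", "mean_a", "mean_b", "fc", "p", "call"]


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def gene_de(
    rpm: pd.DataFrame,
    cells_a,
    cells_b,
    group_a: str = "a",
    group_b: str = "b",
    fc_hi: float = 4.0,
    fc_lo: float = 0.25,
    alpha: float = 0.01,
    floor: float = RPM_FLOOR,
    test: str = "welch",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-gene differential expression between two cell groups.

    Returns a DataFrame with one row per gene (columns ``DE_COLUMNS``).
    Groups of size one get fc but an undefined p (NaN) and call
    ``unchanged``; with ``bh_correct`` p-values are Benjamini-Hochberg
    adjusted before thresholding (default off: raw p < alpha).
    """
    if fc_lo >= fc_hi:
        raise ValueError("need fc_lo < fc_hi")
    test_fn = {"welch": _welch_p, "wilcoxon": _wilcoxon_p}[test]
    A = rpm[list(cells_a)].to_numpy(dtype=float)
    B = rpm[list(cells_b)].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    fc = fold_change(mean_a, mean_b, floor=floor)
    la, lb = np.log2(A + 1.0), np.log2(B + 1.0)
    p = np.array([test_fn(la[i], lb[i]) for i in range(rpm.shape[0])])
    if bh_correct:
        ok = ~np.isnan(p)
        p_adj = p.copy()
        p_adj[ok] = stats.false_discovery_control(p[ok])
        p_eff = p_adj
    else:
        p_eff = p
    call = np.full(rpm.shape[0], "unchanged", dtype=object)
    sig = p_eff < alpha
    call[(fc > fc_hi) & sig] = "up"
    call[(fc < fc_lo) & sig] = "down"
    call[(mean_a <= floor) & (mean_b <= floor)] = "not_expressed"
    return pd.DataFrame(
        {
            "feature": rpm.index,
            "level": "gene",
            "group_a": group_a,
            "group_b": group_b,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fc": fc,
            "p": p_eff,
            "call": call,
        }
    ).reset_index(drop=True)


def variant_counts(
    table: JunctionCountTable, reference: JunctionReference
) -> tuple[pd.DataFrame, list[str]]:
    """Pool discriminating-junction counts per variant.

    Only junctions unique to a variant within its gene attribute reads to
    that variant; variants with no discriminating junction are excluded and
    returned in the ``ambiguous`` list.
    """
    disc = reference.discriminating_junctions()
    counts = table.counts.loc[disc["junction_id"]]
    counts = counts.groupby(disc.set_index("junction_id")["variant_id"]).sum()
    counts.index.name = "variant_id"
    all_variants = reference.entries["variant_id"].unique()
    ambiguous = sorted(set(all_variants) - set(counts.index))
    return counts, ambiguous


def variant_de(
    table: JunctionCountTable,
    reference: JunctionReference,
    sample_a: str,
    sample_b: str,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    alpha: float = 0.01,
    min_counts: int = 5,
    floor: float = RPM_FLOOR,
) -> pd.DataFrame:
    """Per-variant differential expression from pooled junction counts.

    Calls: ``gained`` (0 in b, >= min_counts in a), ``lost`` (symmetric),
    ``up``/``down`` by RPM fold change and Fisher p, ``not_expressed`` when
    neither sample reaches ``min_counts``.
    """
    vc, ambiguous = variant_counts(table, reference)
    lib_a = int(table.library_size[sample_a])
    lib_b = int(table.library_size[sample_b])
    rows = []
    for variant, row in vc.iterrows():
        ca, cb = int(row[sample_a]), int(row[sample_b])
        rpm_a, rpm_b = ca / lib_a * 1e6, cb / lib_b * 1e6
        fc = fold_change(rpm_a, rpm_b, floor=floor)
        if max(ca, cb) < min_counts:
            call, p = "not_expressed", float("nan")
        elif cb == 0 and ca >= min_counts:
            call = "gained"
            p = float(stats.fisher_exact([[ca, lib_a - ca], [cb, lib_b - cb]]).pvalue)
        elif ca == 0 and cb >= min_counts:
            call = "lost"
            p = float(stats.fisher_exact([[ca, lib_a - ca], [cb, lib_b - cb]]).pvalue)
        else:
            p = float(stats.fisher_exact([[ca, lib_a - ca], [cb, lib_b - cb]]).pvalue)
            if fc > fc_hi and p < alpha:
                call = "up"
            elif fc < fc_lo and p < alpha:
                call = "down"
            else:
                call = "unchanged"
        rows.append(
            {
                "feature": variant,
                "level": "variant",
                "group_a": sample_a,
                "group_b": sample_b,
                "mean_a": rpm_a,
                "mean_b": rpm_b,
                "fc": fc,
                "p": p,
                "call": call,
            }
        )
    out = pd.DataFrame(rows, columns=DE_COLUMNS)
    out.attrs["ambiguous_variants"] = ambiguous
    return out


def summarize_de(records: pd.DataFrame) -> dict:
    """Counts of up/down/gained/lost calls and the percent-changed identity.

    ``percent_changed`` is 100 * (n_up + n_down) / n_expressed, where
    expressed features are all rows not called ``not_expressed``.
    """
    calls = records["call"]
    n_expressed = int((calls != "not_expressed").sum())
    n_up = int((calls == "up").sum())
    n_down = int((calls == "down").sum())
    n_changed = n_up + n_down
    return {
        "n_total": int(len(records)),
        "n_expressed": n_expressed,
        "n_up": n_up,
        "n_down": n_down,
        "n_gained": int((calls == "gained").sum()),
        "n_lost": int((calls == "lost").sum()),
        "n_changed": n_changed,
        "percent_changed": 100.0 * n_changed / n_expressed if n_expressed else float("nan"),
    }


def expressed_gene_fraction(rpm: pd.DataFrame, floor: float = RPM_FLOOR) -> dict:
    """Fraction of genes expressed (RPM > floor in at least one cell)."""
    expressed = (rpm > floor).any(axis=1)
    n, total = int(expressed.sum()), int(len(rpm))
    return {
        "n_expressed": n,
        "n_total": total,
        "percent_expressed": 100.0 * n / total if total else float("nan"),
    }


@dataclass(frozen=True)
class PanelSummary:
    """Up/down counts within a curated gene panel."""

    panel: str
    n_panel: int
    n_up: int
    n_down: int

    @property
    def n_changed(self) -> int:
        return self.n_up + self.n_down

    @property
    def percent_changed(self) -> float:
        return 100.0 * self.n_changed / self.n_panel


def panel_summary(
    records: pd.DataFrame,
    panel_genes,
    panel_name: str = "panel",
    change_fold: float = 2.0,
    alpha: float = 0.01,
) -> PanelSummary:
    """Count panel genes changed by |log2 fc| >= log2(change_fold), p < alpha."""
    panel_genes = list(panel_genes)
    if not panel_genes:
        raise ValueError("empty panel")
    sub = records[records["feature"].isin(panel_genes)]
    sig = sub["p"] < alpha
    log_fc = np.log2(sub["fc"].to_numpy(dtype=float))
    thresh = np.log2(change_fold)
    up = int(((log_fc >= thresh) & sig).sum())
    down = int(((log_fc <= -thresh) & sig).sum())
    return PanelSummary(panel=panel_name, n_panel=len(panel_genes), n_up=up, n_down=down)


def pluripotency_score(
    rpm: pd.DataFrame, markers=("Oct4", "Sox2", "Nanog")
) -> pd.Series:
    """Per-cell mean log2(RPM + 1) over the core pluripotency markers."""
    missing = [m for m in markers if m not in rpm.index]
    if missing:
        raise KeyError(f"markers missing from matrix: {missing}")
    return np.log2(rpm.loc[list(markers)] + 1.0).mean(axis=0)


def pluripotency_correlation(
    rpm: pd.DataFrame, genes=None, markers=("Oct4", "Sox2", "Nanog")
) -> pd.Series:
    """Pearson r of each gene's log2(RPM + 1) with the pluripotency score.

    Computed across the supplied cells (e.g. the day-5 Oct4+ / Oct4- mix);
    needs at least three cells.  Genes with zero variance get NaN.
    """
    if rpm.shape[1] < 3:
        raise ValueError("need at least three cells")
    score = pluripotency_score(rpm, markers).to_numpy(dtype=float)
    genes = list(genes) if genes is not None else list(rpm.index)
    X = np.log2(rpm.loc[genes] + 1.0).to_numpy(dtype=float)
    sc = score - score.mean()
    denom_s = np.sqrt((sc**2).sum())
    Xc = X - X.mean(axis=1, keepdims=True)
    denom_x = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ sc) / (denom_x * denom_s)
    return pd.Series(r, index=genes, name="r")
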