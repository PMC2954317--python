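"""Single-cell qPCR (Ct) panels: detection, normalisation, marker gating.

A Ct matrix holds TaqMan cycle-threshold values (genes x cells) with 40 as
the undetected ceiling.  Expression is recovered with the standard
efficiency-2 transform e = 2**(-ct) (ct = 40 mapped to 0) and reported
relative to each gene's mean over all cells of the panel.  Single cells are
gated on the three core pluripotency markers (Oct4, Sox2, Nanog): a cell is
*pluripotent* when all three are detected, *losing* when Oct4 is detected
but Nanog and/or Sox2 is not, and *negative* when Oct4 itself is
undetected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CT_CEILING = 40.0
DEFAULT_CT_THRESHOLD = 32.0
PLURIPOTENCY_MARKERS = ("Oct4", "Sox2", "Nanog")


@dataclass
class CtMatrix:
    """Genes x cells Ct values in [0, 40] plus a per-cell stage label."""

    ct: pd.DataFrame
    stage: pd.Series

    def __post_init__(self) -> None:
        self.stage = pd.Series(self.stage).reindex(self.ct.columns)
        vals = self.ct.to_numpy(dtype=float)
        if np.nanmax(vals, initial=0.0) > CT_CEILING or np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("Ct values must lie in [0, 40]")

    @property
    def genes(self) -> pd.Index:
        return self.ct.index

    @property
    def cells(self) -> pd.Index:
        return self.ct.columns

    def to_csv(self, path) -> None:
        out = pd.concat([self.stage.to_frame("stage").T, self.ct])
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CtMatrix":
        raw = pd.read_csv(path, index_col=0)
        stage = raw.loc["stage"]
        ct = raw.drop(index="stage").astype(float)
        return cls(ct=ct, stage=stage)


def detect(ct, threshold: float = DEFAULT_CT_THRESHOLD):
    """Detection call: True iff ct < threshold (strict).

    Works elementwise on scalars, arrays, Series or DataFrames; values above
    the 40-cycle ceiling are rejected.
    """
    arr = np.asarray(ct, dtype=float)
    if np.nanmax(arr, initial=0.0) > CT_CEILING:
        raise ValueError("Ct above the 40-cycle ceiling")
    if isinstance(ct, (pd.Series, pd.DataFrame)):
        return ct < threshold
    out = arr < threshold
    return bool(out) if out.ndim == 0 else out


def ct_to_expression(ct) -> pd.DataFrame:
    """Efficiency-2 transform 2**(-ct); the undetected ceiling maps to 0."""
    e = np.power(2.0, -np.asarray(ct, dtype=float))
    e[np.asarray(ct, dtype=float) >= CT_CEILING] = 0.0
    if isinstance(ct, pd.DataFrame):
        return pd.DataFrame(e, index=ct.index, columns=ct.columns)
    return e


def normalize_expression(ctm: CtMatrix) -> pd.DataFrame:
    """Per-gene mean-normalised expression across all cells of the panel.

    Each gene's 2**(-ct) values are divided by that gene's mean over all
    cells, so detected genes have gene-wise mean exactly 1.  Genes
    undetected everywhere are reported as all-0 and flagged via the
    ``all_zero`` attribute on the result (no division by zero).
    """
    if ctm.ct.shape[1] < 1:
        raise ValueError("need at least one cell")
    expr = ct_to_expression(ctm.ct)
    means = expr.mean(axis=1)
    zero = means == 0
    safe = means.mask(zero, 1.0)
    norm = expr.div(safe, axis=0)
    norm.attrs["all_zero"] = list(means.index[zero])
    return norm


@dataclass
class GateResult:
    """Per-cell pluripotency state and per-stage marker-loss fractions."""

    state: pd.Series  #: per cell: pluripotent | losing | negative
    fractions: pd.DataFrame  #: per stage counts and percentages


def gate_pluripotency(
    ctm: CtMatrix,
    markers: tuple[str, ...] = PLURIPOTENCY_MARKERS,
    threshold: float = DEFAULT_CT_THRESHOLD,
) -> GateResult:
    """Gate each cell on the marker trio and tabulate per-stage fractions.

    The fraction table reports, per stage, both denominators that appear in
    practice: the *losing* fraction among Oct4-detected cells (e.g. 7/18 of
    day-3 Oct4-high cells missing Nanog and/or Sox2 ~ 39%) and the
    pluripotent fraction among all cells of the stage.  Percentages are
    rounded to the nearest integer for reporting.
    """
    oct4, *others = markers
    for m in markers:
        if m not in ctm.ct.index:
            raise KeyError(f"marker {m!r} missing from the panel")
    det = detect(ctm.ct.loc[list(markers)], threshold)
    oct4_pos = det.loc[oct4]
    all_pos = det.all(axis=0)
    state = pd.Series("negative", index=ctm.cells, name="state")
    state[oct4_pos] = "losing"
    state[all_pos] = "pluripotent"

    rows = []
    for stage, cells in ctm.stage.groupby(ctm.stage):
        idx = cells.index
        if len(idx) == 0:
            raise ValueError(f"stage {stage!r} has no cells")
        n = len(idx)
        n_oct4 = int(oct4_pos[idx].sum())
        n_plur = int((state[idx] == "pluripotent").sum())
        n_losing = int((state[idx] == "losing").sum())
        n_neg = int((state[idx] == "negative").sum())
        rows.append(
            {
                "stage": stage,
                "n_cells": n,
                "n_oct4_detected": n_oct4,
                "n_pluripotent": n_plur,
                "n_losing": n_losing,
                "n_negative": n_neg,
                "losing_of_oct4_pct": round(100 * n_losing / n_oct4) if n_oct4 else 0,
                "pluripotent_of_all_pct": round(100 * n_plur / n),
            }
        )
    fractions = pd.DataFrame(rows).set_index("stage")
    return GateResult(state=state, fractions=fractions)


def marker_dynamics(
    ctm: CtMatrix, gene: str, threshold: float = DEFAULT_CT_THRESHOLD
) -> pd.DataFrame:
    """Per-stage detection fraction, mean normalised expression and CV.

    CV (sd/mean, sample sd) is computed on the gene's normalised expression
    across cells of the stage; it is NaN where the stage mean is 0.
    """
    if gene not in ctm.ct.index:
        raise KeyError(f"gene {gene!r} missing from the panel")
    norm = normalize_expression(ctm).loc[gene]
    det = detect(ctm.ct.loc[gene], threshold)
    rows = []
    for stage, cells in ctm.stage.groupby(ctm.stage):
        idx = cells.index
        vals = norm[idx].to_numpy(dtype=float)
        mean = vals.mean()
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(
            {
                "stage": stage,
                "n_detected": int(det[idx].sum()),
                "n_cells": len(idx),
                "detection_fraction": det[idx].mean(),
                "mean_norm_expression": mean,
                "cv": sd / mean if mean > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("stage")
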