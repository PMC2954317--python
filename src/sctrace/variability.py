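"""Cell-to-cell variability statistics and the transcriptome embedding.

The coefficient of variation (CV = sample standard deviation / mean,
computed across cells of one type) measures expression noise per feature.
Features are stratified by mean expression — high (RPM > 10), mid
(1 < RPM < 10), low (RPM < 1), boundary values falling to the lower
stratum — because measurement noise and biological variability scale
differently with abundance: under pure counting (Poisson) noise
CV = 1/sqrt(mean), so the low stratum is dominated by technical variation
while excess CV in the mid stratum reflects dynamic regulation.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .qpcr_panel import CtMatrix, ct_to_expression, detect

logger = logging.getLogger(__name__)

STRATA_BOUNDS = (1.0, 10.0)
DETECT_RPM = 0.1


def cv(values) -> float:
    """Coefficient of variation: sample (n-1) standard deviation over mean.

    Returns NaN (the undefined flag) when the mean is not positive, e.g. an
    all-zero feature; such features are excluded from density summaries.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("cv needs at least two values")
    mean = arr.mean()
    if mean <= 0:
        return float("nan")
    return float(arr.std(ddof=1) / mean)


def stratify(mean_rpm, bounds: tuple[float, float] = STRATA_BOUNDS):
    """Assign 'low' / 'mid' / 'high' by mean RPM; boundaries go low."""
    lo, hi = bounds
    arr = np.asarray(mean_rpm, dtype=float)
    out = np.where(arr > hi, "high", np.where(arr > lo, "mid", "low"))
    return str(out) if out.ndim == 0 else out


def cv_profile(
    data,
    platform: str = "rnaseq",
    detect_rpm: float = DETECT_RPM,
    ct_threshold: float = 32.0,
    bounds: tuple[float, float] = STRATA_BOUNDS,
) -> pd.DataFrame:
    """Per-feature CV records for one cell group, after the platform filter.

    RNA-seq input is an RPM DataFrame (features x cells); a feature passes
    when its mean RPM > ``detect_rpm``.  qPCR input is a :class:`CtMatrix`;
    a gene passes when Ct < ``ct_threshold`` in at least half of the cells,
    and two CVs are reported — on the raw Ct values and on the 2**(-ct)
    expression scale.

    Returns a DataFrame with columns feature, mean, sd, cv (expression
    scale), cv_ct (qPCR only), stratum, platform.
    """
    if platform == "rnaseq":
        rpm = data
        means = rpm.mean(axis=1)
        keep = means > detect_rpm
        sub = rpm[keep]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        out = pd.DataFrame(
            {
                "feature": sub.index,
                "mean": mean.to_numpy(),
                "sd": sd.to_numpy(),
                "cv": (sd / mean).to_numpy(),
                "stratum": stratify(mean.to_numpy(), bounds),
                "platform": "rnaseq",
            }
        ).reset_index(drop=True)
        return out
    if platform == "qpcr":
        if not isinstance(data, CtMatrix):
            raise TypeError("qPCR profile needs a CtMatrix")
        det = detect(data.ct, ct_threshold)
        keep = det.mean(axis=1) >= 0.5
        ct = data.ct[keep]
        expr = ct_to_expression(ct)
        mean = expr.mean(axis=1)
        sd = expr.std(axis=1, ddof=1)
        cv_expr = (sd / mean.mask(mean == 0)).to_numpy()
        cv_ct = (ct.std(axis=1, ddof=1) / ct.mean(axis=1)).to_numpy()
        return pd.DataFrame(
            {
                "feature": ct.index,
                "mean": mean.to_numpy(),
                "sd": sd.to_numpy(),
                "cv": cv_expr,
                "cv_ct": cv_ct,
                "stratum": pd.array([pd.NA] * len(ct)),  # strata are RPM-defined
                "platform": "qpcr",
            }
        ).reset_index(drop=True)
    raise ValueError(f"unknown platform {platform!r}")


def stratum_summary(profile: pd.DataFrame, quantiles=(0.25, 0.5, 0.75)) -> pd.DataFrame:
    """Per-stratum CV quantiles and counts (undefined CVs excluded)."""
    ok = profile.dropna(subset=["cv"])
    rows = []
    for stratum, grp in ok.groupby("stratum"):
        row = {"stratum": stratum, "n": len(grp)}
        for q in quantiles:
            row[f"q{int(q * 100)}"] = grp["cv"].quantile(q)
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


def embed(
    expression: pd.DataFrame,
    n_components: int = 2,
    log_transform: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component embedding of cells from an RPM matrix.

    Genes with zero variance are dropped; the matrix is log2(RPM + 1)
    transformed (unless ``log_transform`` is off) and mean-centred.  Component
    signs are fixed by making the largest-magnitude gene loading positive, so
    the embedding is deterministic and invariant to gene and cell order.

    Returns (cells x components coordinates, explained variance ratio).
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least two cells")
    X = expression.sort_index(axis=0).sort_index(axis=1).T.to_numpy(dtype=float)
    cells = expression.columns.sort_values()
    if log_transform:
        X = np.log2(X + 1.0)
    X = X[:, X.std(axis=0) > 0]
    rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > rank:
        warnings.warn(
            f"n_components reduced from {n_components} to rank {rank}", stacklevel=2
        )
        n_components = rank
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(n_components):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, k] *= -1
    out = pd.DataFrame(
        coords,
        index=cells,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    ).reindex(expression.columns)
    return out, pca.explained_variance_ratio_
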