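"""QC-driven feature filtering and platform-reliability checks.

Pooled QC injections gauge platform stability: a feature is kept only if it
is detected (present and above an intensity floor, default 1000 cps) in at
least half of the QC replicates and its QC coefficient of variation is at
most 0.3. Reliability of a run is then summarized by pairwise Pearson
correlation between QC injections and by where the QC samples fall in a PCA
of all samples (a stable platform puts them in a tight central cluster).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import FeatureTable

__all__ = [
    "QCReport",
    "detection_rate",
    "coefficient_of_variation",
    "filter_features",
    "qc_reliability",
]

REASON_DETECTION = "detection"
REASON_CV = "cv"


@dataclass
class QCReport:
    """Per-feature QC metrics, keep/remove decisions and reliability stats."""

    detection_rate: pd.Series
    cv: pd.Series
    kept: pd.Series                       # bool per feature
    reasons: dict[str, list[str]]         # feature id -> removal reason codes
    rate_min: float
    cv_max: float
    floor: float
    qc_pairwise_r: pd.DataFrame | None = None
    pca_scores: pd.DataFrame | None = None
    qc_dispersion: float | None = None
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return int((~self.kept).sum())

    def to_dict(self) -> dict:
        out = {
            "rate_min": self.rate_min,
            "cv_max": self.cv_max,
            "floor": self.floor,
            "n_kept": int(self.kept.sum()),
            "n_removed": self.n_removed,
            "detection_rate": self.detection_rate.to_dict(),
            "cv": {k: (None if pd.isna(v) else v) for k, v in self.cv.items()},
            "removed": self.reasons,
        }
        if self.qc_pairwise_r is not None:
            out["qc_pairwise_r"] = self.qc_pairwise_r.to_dict()
        if self.qc_dispersion is not None:
            out["qc_dispersion"] = self.qc_dispersion
        return out


def detection_rate(values, floor: float = 1000.0) -> float:
    """Fraction of QC cells present and at or above the intensity floor."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("detection rate needs at least one QC value")
    return float(np.sum(~np.isnan(arr) & (arr >= floor)) / arr.size)


def coefficient_of_variation(values) -> float:
    """Sample CV (n−1 sd over mean) of the present values."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError("CV needs at least two present values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(arr.std(ddof=1) / mean)


def filter_features(table: FeatureTable, rate_min: float = 0.5,
                    cv_max: float = 0.3, floor: float = 1000.0
                    ) -> tuple[FeatureTable, QCReport]:
    """Drop features failing the QC detection-rate or CV rule.

    A feature is removed iff its QC detection rate is strictly below
    ``rate_min`` or its QC CV is strictly above ``cv_max`` — the boundary
    values 0.5 and 0.3 are kept. Features with fewer than two present QC
    values have no defined CV (recorded as NaN) and fail the detection rule
    anyway whenever ``rate_min`` > 1/n_qc.
    """
    qc = table.qc_matrix()
    if qc.shape[1] < 2:
        raise ValueError("QC filtering needs at least two QC columns")

    rates = {}
    cvs = {}
    reasons: dict[str, list[str]] = {}
    kept = {}
    for fid, row in qc.iterrows():
        rate = detection_rate(row.to_numpy(), floor=floor)
        present = row.to_numpy(dtype=float)
        present = present[~np.isnan(present)]
        cv = (float(present.std(ddof=1) / present.mean())
              if present.size >= 2 and present.mean() > 0 else np.nan)
        rates[fid] = rate
        cvs[fid] = cv
        why = []
        if rate < rate_min:
            why.append(REASON_DETECTION)
        if not np.isnan(cv) and cv > cv_max:
            why.append(REASON_CV)
        kept[fid] = not why
        if why:
            reasons[fid] = why

    kept_s = pd.Series(kept)
    report = QCReport(
        detection_rate=pd.Series(rates), cv=pd.Series(cvs), kept=kept_s,
        reasons=reasons, rate_min=rate_min, cv_max=cv_max, floor=floor,
    )
    filtered = table.subset_features([f for f in table.feature_ids if kept[f]])
    return filtered, report


def qc_reliability(table: FeatureTable, n_components: int = 2
                   ) -> tuple[pd.DataFrame, pd.DataFrame, float, list]:
    """Pairwise QC Pearson correlation and a PCA of all samples.

    Correlations are computed on natural-log intensities over the features
    present in both members of each QC pair; pairs sharing fewer than two
    features are flagged rather than silently NaN. The PCA uses mean-imputed,
    feature-centered log intensities of every sample; the returned dispersion
    statistic is the mean distance of QC samples to the QC centroid divided
    by the mean distance of all samples to the grand centroid (≪1 for a
    stable platform).
    """
    qc = table.qc_matrix()
    if qc.shape[1] < 2:
        raise ValueError("QC reliability needs at least two QC columns")

    with np.errstate(divide="ignore"):
        logqc = np.log(qc.to_numpy(dtype=float))
    logqc[np.isinf(logqc)] = np.nan
    qc_ids = list(qc.columns)
    r = pd.DataFrame(np.eye(len(qc_ids)), index=qc_ids, columns=qc_ids)
    flagged: list[tuple[str, str]] = []
    for i in range(len(qc_ids)):
        for j in range(i + 1, len(qc_ids)):
            a, b = logqc[:, i], logqc[:, j]
            shared = ~np.isnan(a) & ~np.isnan(b)
            if shared.sum() < 2 or a[shared].std() == 0 or b[shared].std() == 0:
                flagged.append((qc_ids[i], qc_ids[j]))
                rij = np.nan
            else:
                rij = float(np.corrcoef(a[shared], b[shared])[0, 1])
            r.iloc[i, j] = r.iloc[j, i] = rij

    # PCA on all samples (rows) over feature axes, mean-imputed log scale
    from sklearn.decomposition import PCA

    with np.errstate(divide="ignore"):
        logx = np.log(table.values.to_numpy(dtype=float))
    logx[np.isinf(logx)] = np.nan
    feat_mean = np.nanmean(logx, axis=1, keepdims=True)
    logx = np.where(np.isnan(logx), feat_mean, logx)
    X = (logx - feat_mean).T  # samples × features, centered per feature
    k = min(n_components, X.shape[0], X.shape[1])
    scores = PCA(n_components=k).fit_transform(X)
    pca_scores = pd.DataFrame(scores, index=table.sample_ids,
                              columns=[f"PC{i + 1}" for i in range(k)])

    is_qc = np.array([s in set(table.qc_samples) for s in table.sample_ids])
    qc_scores = scores[is_qc]
    qc_centroid = qc_scores.mean(axis=0)
    grand_centroid = scores.mean(axis=0)
    qc_spread = float(np.linalg.norm(qc_scores - qc_centroid, axis=1).mean())
    grand_spread = float(np.linalg.norm(scores - grand_centroid, axis=1).mean())
    dispersion = qc_spread / grand_spread if grand_spread > 0 else np.nan
    return r, pca_scores, dispersion, flagged
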