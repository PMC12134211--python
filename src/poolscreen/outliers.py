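"""Density-based detection of traps with deviating phenotypes.

For each fluorescent protein, the per-lineage phenotype points
(maturation time, pre-swap fluorescence) from all replicate
experiments are pooled and clustered with DBSCAN.  The cluster holding
the most points is the major cluster; traps whose lineages unanimously
fall outside it carry a deviating phenotype — typically a mis-decoded
genotype or a rare biological outlier.  Traps with too few lineages or
with split lineage verdicts are excluded, and an FP is only reported
when its major cluster spans more than five traps.

The axes (minutes vs arbitrary fluorescence units) are incommensurate,
so both are standardised to unit variance before clustering by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.preprocessing import StandardScaler

__all__ = ["OutlierParams", "OutlierResult", "detect_outliers"]

LABEL_MAJOR = "major"
LABEL_DEVIATING = "deviating"
LABEL_EXCLUDED = "excluded"


@dataclass(frozen=True)
class OutlierParams:
    """DBSCAN and trap-qualification parameters.

    ``eps`` is in standardised units when ``scaling="standardise"``.
    ``min_lineages_per_trap``: a trap qualifies only with more than two
    lineages (default 3).  ``min_major_cluster_traps``: an FP is
    reported only when its major cluster holds more than five traps
    (default 6).
    """

    eps: float = 0.5
    min_pts: int = 5
    scaling: str = "standardise"  # "standardise" | "none"
    min_lineages_per_trap: int = 3
    min_major_cluster_traps: int = 6

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")
        if self.scaling not in ("standardise", "none"):
            raise ValueError(f"unknown scaling {self.scaling!r}")


@dataclass
class OutlierResult:
    """Per-trap labels and the deviating fraction for one FP.

    ``deviating_fraction`` is deviating / (deviating + major) over
    qualifying traps, or NaN when the FP fails the reporting rule.
    ``all_noise`` flags runs where DBSCAN found no cluster at all.
    ``reported`` is False when the major cluster holds too few traps.
    """

    trap_labels: pd.DataFrame
    deviating_fraction: float
    n_major: int
    n_deviating: int
    n_excluded: int
    reported: bool
    all_noise: bool = False


def detect_outliers(points: pd.DataFrame, params: OutlierParams | None = None) -> OutlierResult:
    """Label each trap of one FP as major / deviating / excluded.

    ``points`` needs columns ``trap_id, lineage_id, tau_m,
    pre_chl_fluorescence`` (one row per lineage, replicates pooled).
    """
    if params is None:
        params = OutlierParams()
    required = {"trap_id", "lineage_id", "tau_m", "pre_chl_fluorescence"}
    missing = required - set(points.columns)
    if missing:
        raise ValueError(f"points missing columns: {sorted(missing)}")
    if len(points) < params.min_pts:
        raise ValueError(f"need >= {params.min_pts} points, got {len(points)}")
    X = points[["tau_m", "pre_chl_fluorescence"]].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite phenotype coordinates")
    if params.scaling == "standardise":
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0  # degenerate axis: leave centred values at 0
        X = (X - X.mean(axis=0)) / scale
    labels = DBSCAN(eps=params.eps, min_samples=params.min_pts).fit_predict(X)

    clusters, counts = np.unique(labels[labels >= 0], return_counts=True)
    if clusters.size == 0:
        trap_labels = (
            points.assign(in_major=False)
            .groupby("trap_id")
            .size()
            .rename("n_lineages")
            .reset_index()
            .assign(label=LABEL_EXCLUDED)
        )
        return OutlierResult(
            trap_labels=trap_labels,
            deviating_fraction=float("nan"),
            n_major=0,
            n_deviating=0,
            n_excluded=points.trap_id.nunique(),
            reported=False,
            all_noise=True,
        )
    major = clusters[counts.argmax()]
    in_major = labels == major

    rows = []
    n_major = n_dev = n_exc = 0
    for trap, idx in points.groupby("trap_id").indices.items():
        verdicts = in_major[idx]
        if len(idx) < params.min_lineages_per_trap or not (
            verdicts.all() or (~verdicts).all()
        ):
            label = LABEL_EXCLUDED
            n_exc += 1
        elif verdicts.all():
            label = LABEL_MAJOR
            n_major += 1
        else:
            label = LABEL_DEVIATING
            n_dev += 1
        rows.append({"trap_id": trap, "n_lineages": len(idx), "label": label})
    trap_labels = pd.DataFrame(rows)
    reported = n_major >= params.min_major_cluster_traps
    frac = n_dev / (n_dev + n_major) if reported and (n_dev + n_major) else float("nan")
    return OutlierResult(
        trap_labels=trap_labels,
        deviating_fraction=frac,
        n_major=n_major,
        n_deviating=n_dev,
        n_excluded=n_exc,
        reported=reported,
    )
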