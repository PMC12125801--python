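"""Seven-metric segmentation evaluation.

Overlap family: DSC, JSC, PPV, SE. Boundary/volume family: HD (symmetric
Hausdorff distance between 8-connected boundary pixel sets, Euclidean pixel
units, optional percentile variant), RVD (absolute relative volume
difference) and VOE (1 - Jaccard). Reports aggregate per-case values as
mean +/- sample SD, excluding flagged undefined cases per metric.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = ["CaseMetrics", "MetricsReport", "overlap_metrics", "hausdorff_distance",
           "volume_metrics", "compute_case_metrics", "evaluate_model",
           "METRIC_NAMES", "HIGHER_IS_BETTER"]

METRIC_NAMES = ("dsc", "jsc", "ppv", "se", "hd", "rvd", "voe")
HIGHER_IS_BETTER = {"dsc": True, "jsc": True, "ppv": True, "se": True,
                    "hd": False, "rvd": False, "voe": False}


def _check_pair(gt: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    gtb = gt.astype(bool)
    predb = pred.astype(bool)
    if not np.array_equal(gt, gtb) and not np.isin(gt, (0, 1)).all():
        raise ValueError("gt must be binary")
    if not np.array_equal(pred, predb) and not np.isin(pred, (0, 1)).all():
        raise ValueError("pred must be binary")
    return gtb, predb


def overlap_metrics(gt: np.ndarray, pred: np.ndarray) -> tuple[float, float, float, float]:
    """(dsc, jsc, ppv, se); NaN marks a metric undefined for this pair."""
    gtb, predb = _check_pair(gt, pred)
    tp = float(np.logical_and(gtb, predb).sum())
    n_gt = float(gtb.sum())
    n_pred = float(predb.sum())
    union = n_gt + n_pred - tp

    dsc = 2.0 * tp / (n_gt + n_pred) if (n_gt + n_pred) > 0 else math.nan
    jsc = tp / union if union > 0 else math.nan
    ppv = tp / n_pred if n_pred > 0 else math.nan
    se = tp / n_gt if n_gt > 0 else math.nan
    return dsc, jsc, ppv, se


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Coordinates of boundary pixels (mask pixels with a background 8-neighbor)."""
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff_distance(gt: np.ndarray, pred: np.ndarray, percentile: float = 100.0) -> float:
    """Symmetric (percentile-)Hausdorff distance between boundary point sets.

    If either mask is empty the distance is undefined; callers use the image
    diagonal as a flagged fallback (see :func:`compute_case_metrics`).
    """
    gtb, predb = _check_pair(gt, pred)
    if not gtb.any() or not predb.any():
        raise ValueError("hausdorff_distance requires two nonempty masks")
    pa = _boundary_points(gtb).astype(np.float64)
    pb = _boundary_points(predb).astype(np.float64)
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    if percentile >= 100.0:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def volume_metrics(gt: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    """(rvd, voe): absolute relative volume difference and volumetric overlap error."""
    gtb, predb = _check_pair(gt, pred)
    n_gt = float(gtb.sum())
    if n_gt == 0:
        raise ValueError("volume metrics require a nonempty ground-truth mask")
    n_pred = float(predb.sum())
    rvd = abs(n_pred - n_gt) / n_gt
    tp = float(np.logical_and(gtb, predb).sum())
    union = n_gt + n_pred - tp
    voe = 1.0 - tp / union if union > 0 else math.nan
    return rvd, voe


@dataclass
class CaseMetrics:
    case_id: str
    dsc: float
    jsc: float
    ppv: float
    se: float
    hd: float
    rvd: float
    voe: float
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"case_id": self.case_id,
                **{m: getattr(self, m) for m in METRIC_NAMES},
                "flags": ";".join(self.flags)}


def compute_case_metrics(gt: np.ndarray, pred: np.ndarray, case_id: str = "",
                         hd_percentile: float = 100.0) -> CaseMetrics:
    """All seven metrics for one pair, with the degenerate-mask policy applied.

    Empty prediction: overlap metrics that involve the prediction become 0
    (PPV stays undefined/flagged), HD falls back to the image diagonal,
    flagged. Empty ground truth: SE and the volume metrics are flagged NaN.
    """
    gtb, predb = _check_pair(gt, pred)
    flags: list[str] = []
    dsc, jsc, ppv, se = overlap_metrics(gtb, predb)
    if not predb.any():
        flags.append("empty_pred")
        ppv = math.nan
        if gtb.any():
            dsc, jsc = 0.0, 0.0
    if not gtb.any():
        flags.append("empty_gt")
        se = math.nan

    if gtb.any() and predb.any():
        hd = hausdorff_distance(gtb, predb, percentile=hd_percentile)
    else:
        hd = float(math.hypot(*gtb.shape))
        flags.append("hd_fallback_diagonal")

    if gtb.any():
        rvd, voe = volume_metrics(gtb, predb)
    else:
        rvd, voe = math.nan, math.nan

    return CaseMetrics(case_id=case_id, dsc=dsc, jsc=jsc, ppv=ppv, se=se,
                       hd=hd, rvd=rvd, voe=voe, flags=flags)


@dataclass
class MetricsReport:
    group_label: str
    per_case: list[CaseMetrics]

    @property
    def aggregate(self) -> dict[str, tuple[float, float]]:
        """mean and sample SD per metric, NaN cases excluded."""
        out = {}
        for m in METRIC_NAMES:
            vals = np.array([getattr(c, m) for c in self.per_case], dtype=np.float64)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                out[m] = (math.nan, math.nan)
            else:
                sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
                out[m] = (float(vals.mean()), sd)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_dict() for c in self.per_case])

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out_dir / f"{self.group_label}_cases.csv", index=False)
        agg = {m: {"mean": mu, "sd": sd} for m, (mu, sd) in self.aggregate.items()}
        with open(out_dir / f"{self.group_label}_aggregate.json", "w") as fh:
            json.dump({"group": self.group_label, "n_cases": len(self.per_case),
                       "aggregate": agg}, fh, indent=2, allow_nan=True)

    def summary(self) -> str:
        parts = [f"{m}={mu:.4f}±{sd:.4f}" for m, (mu, sd) in self.aggregate.items()]
        return f"[{self.group_label}] n={len(self.per_case)} " + " ".join(parts)


def evaluate_model(pairs: list[tuple[np.ndarray, np.ndarray]], label: str = "model",
                   case_ids: list[str] | None = None,
                   hd_percentile: float = 100.0) -> MetricsReport:
    """Per-case metrics plus mean±SD aggregation over (gt, pred) mask pairs."""
    if len(pairs) == 0:
        raise ValueError("evaluate_model requires at least one (gt, pred) pair")
    if case_ids is None:
        case_ids = [f"case_{i:04d}" for i in range(len(pairs))]
    per_case = [
        compute_case_metrics(gt, pred, case_id=cid, hd_percentile=hd_percentile)
        for (gt, pred), cid in zip(pairs, case_ids)
    ]
    return MetricsReport(group_label=label, per_case=per_case)
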