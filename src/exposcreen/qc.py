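"""QC-replicate reproducibility filtering.

Pooled QC injections gauge per-feature technical reproducibility: features
whose relative standard deviation (RSD = 100 * SD / mean, sample SD with
n-1 denominator) across QC samples is not strictly below the threshold are
removed before annotation and statistics.  The default threshold is 50%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msdata import CohortDesign, Feature

__all__ = ["QCStats", "qc_rsd_filter"]


@dataclass(frozen=True)
class QCStats:
    feature_id: str
    mean: float
    sd: float
    rsd: float  # percent; NaN when mean == 0
    retained: bool


def qc_rsd_filter(
    features: list[Feature],
    design: CohortDesign,
    threshold_pct: float = 50.0,
) -> tuple[list[Feature], list[QCStats]]:
    """Retain features with QC RSD strictly below ``threshold_pct``.

    Features with zero QC mean are removed (RSD undefined) rather than
    raising: synthetic blanks and absent features must not crash the
    pipeline.  Stats are emitted for every input feature in input order.
    Requires >= 3 QC samples.
    """
    qc = design.qc_samples
    if len(qc) < 3:
        raise ValueError(f"QC RSD filter needs >= 3 QC samples, got {len(qc)}")
    stats: list[QCStats] = []
    retained: list[Feature] = []
    for f in features:
        vals = np.array([f.intensities.get(s, 0.0) for s in qc], dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if mean > 0:
            rsd = 100.0 * sd / mean
            keep = rsd < threshold_pct
        else:
            rsd = float("nan")
            keep = False
        stats.append(QCStats(f.feature_id, mean, sd, rsd, keep))
        if keep:
            retained.append(f)
    return retained, stats


def qc_stats_frame(stats: list[QCStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [s.feature_id for s in stats],
            "mean": [s.mean for s in stats],
            "sd": [s.sd for s in stats],
            "rsd": [s.rsd for s in stats],
            "retained": [s.retained for s in stats],
        }
    )
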