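"""Fixed-bin rate-coding baseline decoders and model comparison.

A rate-coding model bins the decoding window at one fixed size (20,
50, 100, or 2000 ms) and classifies the binned counts — equivalently,
a single-resolution order-0 B-spline model with no stacking layer. It
reuses the exact fitting path of the main decoder (L1 logistic,
bagging, nested CV), so comparisons against the multi-resolution
ensemble isolate the input representation rather than the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .decoder import DecoderConfig, DecodingResult, nested_cv_fit_predict

__all__ = ["RateModelSpec", "fit_rate_model", "compare_models", "RATE_BIN_SIZES_MS"]

RATE_BIN_SIZES_MS = (20.0, 50.0, 100.0, 2000.0)


@dataclass(frozen=True)
class RateModelSpec:
    bin_ms: float
    order: int = 0


def fit_rate_model(
    ensemble, spec: RateModelSpec, config: DecoderConfig
) -> DecodingResult:
    """Fit one rate-coding baseline with the shared decoder pipeline.

    The bin size must divide the decoding window. ``config`` supplies
    folds, replicas and the L1 grid; its resolution ladder and stacking
    flag are overridden (single order-0 resolution, no meta-learner).
    """
    segments = ensemble.window_ms / spec.bin_ms
    if abs(segments - round(segments)) > 1e-9:
        raise ValueError(
            f"bin size {spec.bin_ms} ms does not divide the "
            f"{ensemble.window_ms} ms window"
        )
    # order-0 features are exact bin counts only if the feature grid is
    # no coarser than the requested bin
    grid_ms = min(config.grid_ms, spec.bin_ms)
    rate_config = replace(
        config,
        segments=(int(round(segments)),),
        order=spec.order,
        grid_ms=grid_ms,
        stack=False,
    )
    return nested_cv_fit_predict(ensemble, rate_config)


def compare_models(mcc_a, mcc_b, label_a: str = "A", label_b: str = "B") -> dict:
    """Paired two-sided comparison of per-(dataset, category) MCCs.

    Inputs must be paired (identical data and splits). Reports the mean
    difference a - b, the paired t statistic and its raw p-value; no
    multiple-testing correction is applied.
    """
    a = np.asarray(mcc_a, dtype=float)
    b = np.asarray(mcc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-D MCC arrays")
    diff = a - b
    if np.allclose(diff, 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(a, b)
    return {
        "label_a": label_a,
        "label_b": label_b,
        "mean_diff": float(diff.mean()),
        "t": float(t),
        "p": float(p),
        "n": int(a.size),
    }


def comparison_table(results: dict) -> pd.DataFrame:
    """Long-form MCC table keyed by (model, category) from a dict of
    named :class:`DecodingResult` objects."""
    rows = []
    for name, res in results.items():
        for cat, mcc in res.mcc_by_category().items():
            rows.append({"model": name, "category": cat, "mcc": mcc})
    return pd.DataFrame(rows)
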