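"""Prediction head and SPSE-based probability calibration.

The raw interaction probability p comes from a logistic MLP over the joint
pair vector.  Calibration multiplies p by exp(-lambda1 * d_geo -
lambda2 * d_diff): pairs that are far apart in meta-path geodesic or
diffusion geometry are damped, never boosted, so p' <= p with equality iff
both penalty terms vanish and ranking within fixed distances is preserved.
The (lambda1, lambda2) grid is tuned by minimizing 15-bin expected
calibration error on validation predictions; auditing also reports the Brier
score, the reliability table and an isotonic-regression post-hoc comparison
(reported, never applied to outputs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Linear, Module, Tensor

__all__ = [
    "PredictionHead",
    "CalibratedPrediction",
    "CalibrationReport",
    "calibrate",
    "tune_lambdas",
    "audit",
    "expected_calibration_error",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = (0.0, 0.01, 0.05, 0.1, 0.2)


class PredictionHead(Module):
    """Logistic MLP d_joint -> 256 -> 1 (hidden width scales at desk size)."""

    def __init__(self, d_joint: int, rng: np.random.Generator, hidden: int = 256, dropout: float = 0.1):
        super().__init__()
        self.l1 = Linear(d_joint, hidden, rng)
        self.l2 = Linear(hidden, 1, rng)
        self.dropout = dropout

    def logits(self, joint: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        h = self.l1(joint).relu()
        if rng is not None:
            h = h.dropout(self.dropout, rng, self.training)
        return self.l2(h)

    def __call__(self, joint: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        return self.logits(joint, rng).sigmoid()


@dataclass
class CalibratedPrediction:
    p_dti: float
    d_geo: float
    d_diff: float
    lambda1: float
    lambda2: float

    @property
    def p_calibrated(self) -> float:
        return float(calibrate(self.p_dti, self.d_geo, self.d_diff, self.lambda1, self.lambda2))


def calibrate(p, d_geo, d_diff, lambda1: float, lambda2: float):
    """p' = p * exp(-lambda1 * d_geo - lambda2 * d_diff)."""
    p = np.asarray(p, dtype=np.float64)
    d_geo = np.asarray(d_geo, dtype=np.float64)
    d_diff = np.asarray(d_diff, dtype=np.float64)
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalty strengths must be nonnegative")
    if (d_geo < 0).any() or (d_diff < 0).any():
        raise ValueError("distances must be nonnegative")
    return p * np.exp(-lambda1 * d_geo - lambda2 * d_diff)


def expected_calibration_error(p: np.ndarray, y: np.ndarray, n_bins: int = 15):
    """Equal-width binned |accuracy - confidence| gap; returns (ECE, table)."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty predictions")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    ece = 0.0
    table = []
    for b in range(n_bins):
        m = which == b
        n_b = int(m.sum())
        if n_b == 0:
            table.append({"bin": b, "n": 0, "confidence": np.nan, "accuracy": np.nan})
            continue
        conf = float(p[m].mean())
        acc = float(y[m].mean())
        ece += (n_b / p.size) * abs(acc - conf)
        table.append({"bin": b, "n": n_b, "confidence": conf, "accuracy": acc})
    return float(ece), table


def tune_lambdas(
    p_raw: np.ndarray,
    y: np.ndarray,
    d_geo: np.ndarray,
    d_diff: np.ndarray,
    grid: tuple = DEFAULT_LAMBDA_GRID,
) -> tuple[float, float]:
    """Grid-search (lambda1, lambda2) minimizing 15-bin ECE of p'; ties break
    toward smaller lambda1 + lambda2 (then lexicographically)."""
    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    if len(p_raw) == 0:
        raise ValueError("empty validation set")
    best = None
    for l1 in grid:
        for l2 in grid:
            pc = calibrate(p_raw, d_geo, d_diff, l1, l2)
            ece, _ = expected_calibration_error(pc, y)
            key = (round(ece, 12), l1 + l2, l1, l2)
            if best is None or key < best[0]:
                best = (key, (float(l1), float(l2)))
    return best[1]


@dataclass
class CalibrationReport:
    ece: float
    brier: float
    reliability: list
    isotonic_ece: float
    isotonic_brier: float
    n: int


def audit(p: np.ndarray, y: np.ndarray, n_bins: int = 15) -> CalibrationReport:
    """ECE (15 equal-width bins), Brier score, reliability table and an
    isotonic-regression comparison (audit only)."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.size == 0 or p.size != y.size:
        raise ValueError("predictions and labels must be same-length and nonempty")
    ece, table = expected_calibration_error(p, y, n_bins)
    brier = float(np.mean((p - y) ** 2))
    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(out_of_bounds="clip", y_min=0.0, y_max=1.0)
    p_iso = iso.fit_transform(p, y)
    iso_ece, _ = expected_calibration_error(p_iso, y, n_bins)
    iso_brier = float(np.mean((p_iso - y) ** 2))
    return CalibrationReport(
        ece=ece, brier=brier, reliability=table,
        isotonic_ece=iso_ece, isotonic_brier=iso_brier, n=int(p.size),
    )
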