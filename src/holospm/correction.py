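"""Coarse-PM mixture correction.

The low-pass branch cannot fully remove fine-PM speckle, so a coarse model
fed mixture images over-predicts.  The remedy has three steps:

1. feed low-pass-filtered *fine-only* stacks to the coarse model and fit
   the misprediction line Y = A X + B (X = fine concentration);
2. grid-search the correction coefficient k minimizing the RMSE of the
   corrected predictions P_c = P - k Y on labeled mixtures, with Y
   evaluated at the fine branch's own prediction X-hat (the fine
   concentration must be measurable in advance);
3. apply P_c = P - k (A X-hat + B), clipping negative results to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import HoloSpeckleNet, percent_error, predict_concentration, rmse
from .preprocess import COARSE_BRANCH, FINE_BRANCH, PreprocParams

logger = logging.getLogger(__name__)

__all__ = [
    "CorrectionModel",
    "measure_leakage",
    "fit_misprediction_line",
    "optimize_k",
    "apply_correction",
    "evaluate_pipeline",
]


@dataclass(frozen=True)
class CorrectionModel:
    """Misprediction line (A, B) plus correction coefficient k at filter R."""

    slope: float       # A: predicted-coarse per true-fine (dimensionless)
    intercept: float   # B: ug/ml
    k: float           # dimensionless
    filter_size: float = 20.0
    fitted_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")

    def leakage(self, x_hat) -> np.ndarray:
        """Y = A X-hat + B, the mispredicted coarse concentration."""
        return self.slope * np.asarray(x_hat, float) + self.intercept


def measure_leakage(coarse_model: HoloSpeckleNet,
                    fine_stacks: dict[float, list],
                    params: PreprocParams = COARSE_BRANCH
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Coarse-branch predictions on monodisperse-fine stacks.

    ``fine_stacks`` maps true fine concentration (ug/ml) -> list of raw
    frames.  Returns (X, Y): per-class true fine concentration and the
    class-mean coarse prediction it spuriously produces.  Zero-concentration
    (blank) classes are recorded, not discarded: they pin the intercept.
    """
    if len(fine_stacks) < 2:
        raise ValueError("need >= 2 fine concentrations to measure leakage")
    x, y = [], []
    for conc in sorted(fine_stacks):
        record = predict_concentration(coarse_model, fine_stacks[conc],
                                       params=params)
        x.append(conc)
        y.append(record.class_mean)
    return np.array(x), np.array(y)


def fit_misprediction_line(x, y) -> tuple[float, float]:
    """Ordinary least squares over class means: Y = A X + B."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct X values")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def optimize_k(p, x_hat, line: tuple[float, float], truth,
               k_grid: np.ndarray | None = None
               ) -> tuple[float, np.ndarray, np.ndarray]:
    """Grid-search k minimizing RMSE(P - k (A X-hat + B), truth).

    Default grid is k in [0, 1.5] step 0.01; ties resolve to the smallest
    k.  Returns (k_opt, grid, rmse_curve) so the search curve can be
    inspected or plotted.
    """
    p, x_hat, truth = (np.asarray(v, float) for v in (p, x_hat, truth))
    if not (p.shape == x_hat.shape == truth.shape):
        raise ValueError("P, X-hat and truth must align")
    if k_grid is None:
        k_grid = np.round(np.arange(0.0, 1.5 + 1e-9, 0.01), 10)
    k_grid = np.asarray(k_grid, float)
    if k_grid.size == 0:
        raise ValueError("empty k grid")
    slope, intercept = line
    y = slope * x_hat + intercept
    curve = np.array([rmse(p - k * y, truth) for k in k_grid])
    k_opt = float(k_grid[int(np.argmin(curve))])  # argmin takes first = smallest k
    return k_opt, k_grid, curve


def apply_correction(p, x_hat, model: CorrectionModel) -> np.ndarray:
    """P_c = P - k (A X-hat + B); negatives clipped to zero and flagged."""
    p = np.asarray(p, float)
    corrected = p - model.k * model.leakage(x_hat)
    if np.any(corrected < 0):
        logger.warning("corrected coarse concentration clipped to 0 for %d "
                       "of %d classes", int(np.sum(corrected < 0)), p.size)
        corrected = np.clip(corrected, 0.0, None)
    return corrected


def evaluate_pipeline(mixture_stacks: dict[tuple[float, float], list],
                      fine_model: HoloSpeckleNet,
                      coarse_model: HoloSpeckleNet,
                      correction: CorrectionModel,
                      fine_params: PreprocParams = FINE_BRANCH,
                      coarse_params: PreprocParams = COARSE_BRANCH
                      ) -> pd.DataFrame:
    """Per-class fine/coarse predictions on labeled mixtures, pre/post correction.

    ``mixture_stacks`` maps (rho_f, rho_c) -> list of raw frames.  Returns a
    tidy DataFrame with one row per mixture class; summary percent errors
    and RMSEs are attached in ``DataFrame.attrs["summary"]``.
    """
    if len(mixture_stacks) == 0:
        raise ValueError("no mixture classes given")
    rows = []
    for (rho_f, rho_c), frames in sorted(mixture_stacks.items()):
        if frames[0].labels is None:
            raise ValueError("mixture frames must carry labels")
        fine_rec = predict_concentration(fine_model, frames, params=fine_params)
        coarse_rec = predict_concentration(coarse_model, frames,
                                           params=coarse_params)
        p_c = float(apply_correction(coarse_rec.class_mean, fine_rec.class_mean,
                                     correction))
        rows.append({"rho_f_true": rho_f, "rho_c_true": rho_c,
                     "rho_f_pred": fine_rec.class_mean,
                     "rho_c_pred_raw": coarse_rec.class_mean,
                     "rho_c_pred_corrected": p_c})
    report = pd.DataFrame(rows)
    summary = {}
    for col, truth_col in (("rho_f_pred", "rho_f_true"),
                           ("rho_c_pred_raw", "rho_c_true"),
                           ("rho_c_pred_corrected", "rho_c_true")):
        truth = report[truth_col].to_numpy()
        pred = report[col].to_numpy()
        nonzero = truth > 0
        summary[f"rmse_{col}"] = rmse(pred, truth)
        if np.any(nonzero):
            m, s = percent_error(pred[nonzero], truth[nonzero])
            summary[f"pct_err_{col}"] = (m, s)
    report.attrs["summary"] = summary
    return report
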