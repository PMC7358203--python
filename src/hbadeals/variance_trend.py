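"""Voom-style mean-variance trend for log-cpm observations.

Count data on the log-cpm scale shows a systematic relation between a row's
mean level and its variability.  Following the voom approach, a two-group
linear model (intercept plus condition indicator) is fit to each row, and a
LOWESS curve relates the square root of the residual standard deviation to
the row's mean log-cpm.  Per-observation variances are then read back from
the curve at each observation's fitted value (its condition mean) and raised
to the 4th power, undoing the square-root-of-sd scale of the fit.

The trend is fitted separately for the gene-level and isoform-level matrices;
each yields its own :class:`VarianceTrend`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_normalize import LogCpmMatrix

__all__ = ["VarianceTrend", "fit_trend", "observation_variances"]


@dataclass
class VarianceTrend:
    """Monotone-interpolable curve: mean log-cpm -> predicted sqrt(sd).

    Evaluation outside ``support_range`` clamps to the boundary values.
    """

    x: np.ndarray  # sorted abscissae (mean log-cpm)
    y: np.ndarray  # smoothed sqrt(residual sd) at each abscissa

    @property
    def support_range(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])

    def __call__(self, at) -> np.ndarray:
        """Predicted sqrt(sd), linearly interpolated with boundary clamping."""
        at = np.asarray(at, dtype=float)
        return np.interp(at, self.x, self.y)  # np.interp clamps at the edges

    def variance(self, at) -> np.ndarray:
        """Predicted variance: 4th power of the sqrt(sd) curve value."""
        return self(at) ** 4


def _row_fits(values: np.ndarray, is_control: np.ndarray):
    """Residual sd and condition means of the two-group-means model per row.

    Returns (sd, mean_all, mean_control, mean_case); sd uses n-2 degrees of
    freedom.
    """
    n = values.shape[1]
    nc = int(is_control.sum())
    nk = n - nc
    mc = values[:, is_control].mean(axis=1)
    mk = values[:, ~is_control].mean(axis=1)
    rss = ((values[:, is_control] - mc[:, None]) ** 2).sum(axis=1)
    rss += ((values[:, ~is_control] - mk[:, None]) ** 2).sum(axis=1)
    dof = max(n - 2, 1)
    sd = np.sqrt(rss / dof)
    mean_all = (nc * mc + nk * mk) / n
    return sd, mean_all, mc, mk


def fit_trend(
    logcpm: LogCpmMatrix,
    span: float = 0.5,
    iterations: int = 3,
) -> VarianceTrend:
    """Fit the LOWESS curve of sqrt(residual sd) against mean log-cpm.

    Parameters
    ----------
    logcpm
        Log-cpm matrix; both conditions must be present.
    span
        LOWESS smoothing fraction.
    iterations
        Robustifying reweighting iterations.
    """
    is_control = logcpm.is_control
    if is_control.all() or not is_control.any():
        raise ValueError("both conditions must be present to fit the trend")
    values = logcpm.values
    if values.shape[0] < 10:
        warnings.warn(
            f"fitting a mean-variance trend on only {values.shape[0]} rows; "
            "estimates may be unstable",
            UserWarning,
            stacklevel=2,
        )
    sd, mean_all, _, _ = _row_fits(values, is_control)
    if np.all(sd == 0):
        raise ValueError("degenerate variance structure: all residual sds are zero")
    sqrt_sd = np.sqrt(sd)
    fitted = lowess(
        sqrt_sd, mean_all, frac=span, it=iterations, return_sorted=True
    )
    x, y = fitted[:, 0], fitted[:, 1]
    # collapse duplicated abscissae so interpolation is well defined
    ux, inv = np.unique(x, return_inverse=True)
    uy = np.zeros_like(ux)
    cnt = np.zeros_like(ux)
    np.add.at(uy, inv, y)
    np.add.at(cnt, inv, 1.0)
    uy /= cnt
    uy = np.maximum(uy, 1e-6)  # the readback variance must stay positive
    return VarianceTrend(x=ux, y=uy)


def observation_variances(
    trend: VarianceTrend, logcpm: LogCpmMatrix
) -> np.ndarray:
    """Per-observation variances from the fitted trend.

    Each observation's abscissa is its fitted value under the two-group model,
    i.e. the condition-specific mean log-cpm of its row; the returned matrix
    has ``trend(fitted)**4`` in every cell and is strictly positive.
    """
    is_control = logcpm.is_control
    _, _, mc, mk = _row_fits(logcpm.values, is_control)
    out = np.empty_like(logcpm.values)
    out[:, is_control] = trend.variance(mc)[:, None]
    out[:, ~is_control] = trend.variance(mk)[:, None]
    return out
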