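"""Dose/time response fitting (four-parameter logistic), FRAP and ΔΔCt.

The central object is :class:`FourParamLogistic`, a small model class in the
model/results idiom: build it from arrays or a long-format DataFrame, call
``fit()``, and get a :class:`ResponseFit` results object carrying parameter
estimates, standard errors, diagnostics and a ``summary()`` table. The
midpoint is reported as IC50 for dose data and t1/2 for time data.

The module also houses the 1D synthetic generators used to exercise the
fits (noisy logistic series and FRAP recovery traces), FRAP pre-bleach
normalization, and relative qPCR quantification (2^−ΔΔCt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "logistic4",
    "ResponseSeries",
    "FourParamLogistic",
    "ResponseFit",
    "fit_4pl",
    "summarize_halfmax",
    "FrapTrace",
    "frap_normalize",
    "ddct_fold_change",
    "simulate_dose_series",
    "simulate_frap_trace",
]


def logistic4(x, bottom: float, top: float, midpoint: float, hill: float) -> np.ndarray:
    """Four-parameter logistic ``bottom + (top − bottom)/(1 + (x/midpoint)^hill)``.

    With ``hill > 0`` the curve falls from ``top`` (x → 0) to ``bottom``
    (x → ∞); the sign of ``hill`` encodes the direction of the response.
    ``x = 0`` is handled by its limit.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        u = np.power(x / midpoint, hill)
        u = np.where(np.isfinite(u), u, np.inf)
    return bottom + (top - bottom) / (1.0 + u)


@dataclass
class ResponseSeries:
    """A dose– or time–response series.

    ``x`` is concentration (log-scale fitting) or time (linear);
    ``y`` the response (percent-positive or a normalized signal); replicates
    at the same x are kept as separate points.
    """

    x: np.ndarray
    y: np.ndarray
    replicate: np.ndarray | None = None
    x_scale: str = "log"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if self.x_scale not in ("log", "linear"):
            raise ValueError("x_scale must be 'log' or 'linear'")
        if self.x_scale == "log" and np.any(self.x <= 0):
            raise ValueError("log-scale fitting requires x > 0")
        if np.any(self.x < 0):
            raise ValueError("x must be >= 0")
        if np.unique(self.x).size < 4:
            raise ValueError("a 4-parameter fit needs >= 4 distinct x values")


@dataclass
class ResponseFit:
    """Results of a four-parameter logistic fit.

    After canonicalization ``bottom <= top`` (flipping the sign of ``hill``
    preserves the curve), and ``midpoint > 0`` by parameterization.
    """

    bottom: float
    top: float
    midpoint: float
    hill: float
    bse: dict = field(default_factory=dict)
    residual_sd: float = float("nan")
    converged: bool = False
    n_obs: int = 0
    x_scale: str = "log"
    message: str = ""

    @property
    def params(self) -> dict:
        return {
            "bottom": self.bottom,
            "top": self.top,
            "midpoint": self.midpoint,
            "hill": self.hill,
        }

    def predict(self, x) -> np.ndarray:
        return logistic4(x, self.bottom, self.top, self.midpoint, self.hill)

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic fit",
            "=" * 46,
            f"{'n obs':<14}{self.n_obs:>10}",
            f"{'x scale':<14}{self.x_scale:>10}",
            f"{'converged':<14}{str(self.converged):>10}",
            f"{'residual sd':<14}{self.residual_sd:>10.4g}",
            "-" * 46,
            f"{'param':<10}{'estimate':>14}{'std err':>14}",
        ]
        for name, value in self.params.items():
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name:<10}{value:>14.5g}{se:>14.3g}")
        lines.append("=" * 46)
        return "\n".join(lines)


class FourParamLogistic:
    """Four-parameter logistic model for a response series.

    Parameters
    ----------
    x, y : array-like
        Doses (or times) and responses; replicates are separate points.
    x_scale : {"log", "linear"}
        "log" for dose data (the midpoint is fitted on a log10 axis),
        "linear" for time courses.

    Examples
    --------
    >>> model = FourParamLogistic([1, 3, 10, 30, 100], [90, 80, 50, 20, 10])
    >>> res = model.fit()
    >>> round(res.midpoint, 1)
    10.0
    """

    def __init__(self, x, y, x_scale: str = "log") -> None:
        self.series = ResponseSeries(x=np.asarray(x), y=np.asarray(y), x_scale=x_scale)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, x: str = "x", y: str = "y", x_scale: str = "log"
    ) -> "FourParamLogistic":
        return cls(df[x].to_numpy(), df[y].to_numpy(), x_scale=x_scale)

    def _initial_guess(self) -> np.ndarray:
        x, y = self.series.x, self.series.y
        bottom0, top0 = float(np.min(y)), float(np.max(y))
        mid_resp = 0.5 * (bottom0 + top0)
        pos = x[x > 0]
        mid0 = float(pos[np.argmin(np.abs(self.series.y[x > 0] - mid_resp))]) if pos.size else 1.0
        # trend sign: response falling with x means hill > 0 in this form
        order = np.argsort(x)
        trend = np.polyfit(np.arange(x.size), y[order], 1)[0]
        hill0 = 1.0 if trend < 0 else -1.0
        return np.array([bottom0, top0, np.log10(max(mid0, 1e-12)), hill0])

    def fit(self, max_nfev: int = 2000) -> ResponseFit:
        """Unweighted least-squares fit; non-convergence is flagged, not hidden."""
        x, y = self.series.x, self.series.y

        def residuals(theta):
            bottom, top, log_mid, hill = theta
            return logistic4(x, bottom, top, 10.0**log_mid, hill) - y

        theta0 = self._initial_guess()
        sol = least_squares(residuals, theta0, max_nfev=max_nfev)
        bottom, top, log_mid, hill = sol.x
        midpoint = float(10.0**log_mid)
        if bottom > top:  # canonical form: bottom <= top, hill sign flipped
            bottom, top, hill = top, bottom, -hill

        n, p = y.size, 4
        dof = max(n - p, 1)
        residual_sd = float(np.sqrt(2.0 * sol.cost / dof))
        converged = bool(sol.success and np.all(np.isfinite(sol.x)))

        bse: dict = {}
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj) * residual_sd**2
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            # d(midpoint)/d(log_mid) = ln(10) * midpoint
            bse = {
                "bottom": float(se[0]),
                "top": float(se[1]),
                "midpoint": float(se[2] * np.log(10.0) * midpoint),
                "hill": float(se[3]),
            }
        except np.linalg.LinAlgError:  # singular Jacobian: leave errors empty
            pass

        if not converged:
            logger.warning("4PL fit did not converge: %s", sol.message)
        return ResponseFit(
            bottom=float(bottom),
            top=float(top),
            midpoint=midpoint,
            hill=float(hill),
            bse=bse,
            residual_sd=residual_sd,
            converged=converged,
            n_obs=int(n),
            x_scale=self.series.x_scale,
            message=str(sol.message),
        )


def fit_4pl(series: ResponseSeries) -> ResponseFit:
    """Fit a four-parameter logistic to a :class:`ResponseSeries`."""
    return FourParamLogistic(series.x, series.y, x_scale=series.x_scale).fit()


def summarize_halfmax(fit: ResponseFit, mode: str) -> dict:
    """Label a converged fit's midpoint as IC50 (dose) or t1/2 (time).

    An unconverged fit yields a missing value, never a silent number.
    """
    if mode not in ("dose", "time"):
        raise ValueError("mode must be 'dose' or 'time'")
    name = "IC50" if mode == "dose" else "t1/2"
    units = "concentration units" if mode == "dose" else "time units"
    if not fit.converged:
        logger.warning("half-max summary unavailable: fit did not converge")
        return {"name": name, "value": float("nan"), "units": units}
    return {"name": name, "value": fit.midpoint, "units": units}


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

@dataclass
class FrapTrace:
    """A fluorescence-recovery trace: ROI mean intensity sampled at a fixed
    interval, with the photobleach at frame ``bleach_index`` (>= 1 so that at
    least one pre-bleach frame exists)."""

    intensity: np.ndarray
    sampling_interval_s: float = 0.9456
    bleach_index: int = 1

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1 or self.intensity.size < 2:
            raise ValueError("a FRAP trace needs >= 2 frames")
        if not (1 <= self.bleach_index < self.intensity.size):
            raise ValueError("bleach_index must leave >= 1 pre-bleach frame")

    @property
    def time_s(self) -> np.ndarray:
        return self.sampling_interval_s * np.arange(self.intensity.size)


def frap_normalize(trace: FrapTrace) -> pd.DataFrame:
    """Divide the trace by its mean pre-bleach intensity.

    The pre-bleach segment of the output has mean exactly 1. A zero
    pre-bleach mean leaves normalization undefined (raises).
    """
    pre = trace.intensity[: trace.bleach_index]
    ref = float(np.mean(pre))
    if ref == 0:
        raise ValueError("pre-bleach mean is zero; normalization undefined")
    return pd.DataFrame(
        {
            "time_s": trace.time_s,
            "normalized_intensity": trace.intensity / ref,
            "prebleach": np.arange(trace.intensity.size) < trace.bleach_index,
        }
    )


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def ddct_fold_change(
    ct: pd.DataFrame,
    *,
    target: str,
    reference: str,
    control_condition: str,
    gene_col: str = "gene",
    condition_col: str = "condition",
    ct_col: str = "ct",
) -> pd.DataFrame:
    """Relative expression by the ΔΔCt method.

    Per condition, ΔCt = mean(target Ct) − mean(reference Ct); ΔΔCt is taken
    against the control condition and fold change = 2^(−ΔΔCt), so the
    control's fold change is 1 by construction. Replicate spread is emitted
    as ``fold_change_sd`` (ΔCt standard deviations combined in quadrature
    and propagated through the exponential).
    """
    genes = set(ct[gene_col])
    if reference not in genes:
        raise ValueError(f"reference gene {reference!r} missing from the Ct table")
    if target not in genes:
        raise ValueError(f"target gene {target!r} missing from the Ct table")
    if control_condition not in set(ct[condition_col]):
        raise ValueError(f"control condition {control_condition!r} missing")
    if not np.all(np.isfinite(ct[ct_col].to_numpy(dtype=float))):
        raise ValueError("Ct values must be finite")

    stats = (
        ct[ct[gene_col].isin([target, reference])]
        .groupby([condition_col, gene_col])[ct_col]
        .agg(["mean", "std", "count"])
    )
    rows = []
    dct_control = (
        stats.loc[(control_condition, target), "mean"]
        - stats.loc[(control_condition, reference), "mean"]
    )
    for cond in ct[condition_col].unique():
        t = stats.loc[(cond, target)]
        r = stats.loc[(cond, reference)]
        dct = float(t["mean"] - r["mean"])
        ddct = dct - float(dct_control)
        fold = float(2.0 ** (-ddct))
        sd_dct = float(np.sqrt(np.nan_to_num(t["std"]) ** 2 + np.nan_to_num(r["std"]) ** 2))
        rows.append(
            {
                "condition": cond,
                "delta_ct": dct,
                "delta_delta_ct": ddct,
                "fold_change": fold,
                "fold_change_sd": float(np.log(2.0) * fold * sd_dct),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 1D synthetic series (for exercising the fits)
# ---------------------------------------------------------------------------

def simulate_dose_series(
    *,
    bottom: float = 5.0,
    top: float = 85.0,
    midpoint: float = 11.37,
    hill: float = -1.5,
    doses: np.ndarray | None = None,
    n_replicates: int = 3,
    noise_frac: float = 0.05,
    rng: np.random.Generator | None = None,
    x_scale: str = "log",
) -> ResponseSeries:
    """Noisy logistic series mimicking a percent-positive dose response.

    Defaults: a curve rising from ~5% to ~85% (hill < 0 increases with dose
    in this parameterization) with slope magnitude 1.5, sampled on an
    8-point 3-fold serial dilution centred on the midpoint — the standard
    IC50 plate design — with multiplicative Gaussian replicate noise
    (sd = noise_frac · signal, the usual constant-CV model for
    fluorescence-derived readouts).
    """
    rng = rng or np.random.default_rng(0)
    if doses is None:
        doses = midpoint * 3.0 ** np.arange(-3.5, 4.0, 1.0)
    x = np.repeat(doses, n_replicates)
    y = logistic4(x, bottom, top, midpoint, hill)
    if noise_frac > 0:
        y = y * (1.0 + rng.normal(0.0, noise_frac, size=y.shape))
    return ResponseSeries(x=x, y=y, x_scale=x_scale)


def simulate_frap_trace(
    *,
    n_frames: int = 120,
    bleach_index: int = 10,
    initial: float = 100.0,
    bleach_depth: float = 0.8,
    mobile_fraction: float = 0.4,
    tau_s: float = 12.0,
    sampling_interval_s: float = 0.9456,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> FrapTrace:
    """Single-exponential recovery trace with partial mobile fraction,
    mimicking the slow, incomplete recovery of gel-like reporter puncta."""
    rng = rng or np.random.default_rng(0)
    t = sampling_interval_s * np.arange(n_frames)
    post = t[bleach_index:] - t[bleach_index]
    bleached = initial * (1.0 - bleach_depth)
    plateau = bleached + mobile_fraction * (initial - bleached)
    trace = np.concatenate(
        [
            np.full(bleach_index, initial),
            plateau - (plateau - bleached) * np.exp(-post / tau_s),
        ]
    )
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=trace.shape)
    return FrapTrace(
        intensity=np.clip(trace, 0, None),
        sampling_interval_s=sampling_interval_s,
        bleach_index=bleach_index,
    )
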