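"""Linear standard curve and inverse prediction of DNA amount.

The standards are plotted exactly as in the source protocol: net DAPI
intensity (response, y) against genome size in kb (predictor, x), and the
best-fit ordinary least squares line is inverted to convert an unknown's
net intensity to kilobases,

    kb_hat = (net - intercept) / slope.

A 95% interval for the unknown comes from the inverse-prediction delta
method using the fit's parameter covariance plus the single-observation
residual variance; a Fieller interval is available for noisy/low-slope
fits where the delta approximation degrades.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import PHAGE_GENOME_KB
from .errors import IncompleteStandardSetError, NonPositiveSlopeError, UnderdeterminedError
from .standards import StandardPoint

REQUIRED_KB = tuple(sorted(PHAGE_GENOME_KB.values()))  # (48, 90, 168)


@dataclass
class CalibrationFit:
    """Fitted linear standard: intensity = intercept + slope * kb."""

    slope: float                 # intensity per kb (> 0)
    intercept: float             # intensity
    r_squared: float
    residual_sd: float           # intensity, n-2 degrees of freedom
    param_covariance: np.ndarray  # 2x2, order (intercept, slope)
    n_points: int
    points: tuple[StandardPoint, ...] = ()
    session: str = ""

    def predict_intensity(self, kb: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * kb

    # -- serialization as flat key-value text -------------------------------

    def to_text(self, path: str | Path) -> None:
        c = self.param_covariance
        lines = [
            f"session = {self.session}",
            f"slope = {float(self.slope)!r}",
            f"intercept = {float(self.intercept)!r}",
            f"r_squared = {float(self.r_squared)!r}",
            f"residual_sd = {float(self.residual_sd)!r}",
            f"cov_intercept_intercept = {float(c[0, 0])!r}",
            f"cov_intercept_slope = {float(c[0, 1])!r}",
            f"cov_slope_slope = {float(c[1, 1])!r}",
            f"n_points = {self.n_points}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "CalibrationFit":
        kv = {}
        for line in Path(path).read_text().splitlines():
            if "=" in line:
                key, val = line.split("=", 1)
                kv[key.strip()] = val.strip()
        cov = np.array([[float(kv["cov_intercept_intercept"]), float(kv["cov_intercept_slope"])],
                        [float(kv["cov_intercept_slope"]), float(kv["cov_slope_slope"])]])
        return cls(slope=float(kv["slope"]), intercept=float(kv["intercept"]),
                   r_squared=float(kv["r_squared"]), residual_sd=float(kv["residual_sd"]),
                   param_covariance=cov, n_points=int(kv["n_points"]),
                   session=kv.get("session", ""))


@dataclass
class DnaEstimate:
    """Inverse-predicted DNA amount for one measured net intensity."""

    kb: float
    ci_low: float
    ci_high: float
    net_intensity: float
    method: str = "delta"
    flags: frozenset[str] = frozenset()


def fit_standard_curve(
    points: Sequence[StandardPoint], session: str = ""
) -> CalibrationFit:
    """OLS fit of net intensity on genome kb over the standard points.

    Requires >= 3 points with all three genome sizes represented, and a
    strictly positive fitted slope.
    """
    if len(points) < 3:
        raise UnderdeterminedError(f"need >= 3 standard points, got {len(points)}")
    kb = np.array([p.genome_kb for p in points], dtype=float)
    y = np.array([p.net_intensity for p in points], dtype=float)
    present = set(np.round(kb, 6))
    if not set(REQUIRED_KB) <= present:
        raise IncompleteStandardSetError(
            f"incomplete standard set: sizes present {sorted(present)}")
    model = sm.OLS(y, sm.add_constant(kb)).fit()
    intercept, slope = model.params
    if slope <= 0:
        raise NonPositiveSlopeError(f"non-positive calibration slope: {slope:.4g}")
    # Perfect fits make centred R^2 degenerate through 0/0; define as 1.
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else float(model.rsquared)
    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        residual_sd=float(np.sqrt(model.scale)),
        param_covariance=np.asarray(model.cov_params()),
        n_points=len(points),
        points=tuple(points),
        session=session,
    )


def predict_dna(
    fit: CalibrationFit,
    net_intensity: float,
    confidence: float = 0.95,
    method: str = "delta",
) -> DnaEstimate:
    """Invert the standard line for one observed net intensity.

    ``method`` is ``delta`` (default) or ``fieller``. Negative estimates are
    possible (intensity below the fitted intercept) and are flagged, never
    clamped.
    """
    if fit.slope <= 0:
        raise NonPositiveSlopeError("fit has non-positive slope")
    y0 = float(net_intensity)
    kb = (y0 - fit.intercept) / fit.slope
    df = max(fit.n_points - 2, 1)
    tcrit = stats.t.ppf(0.5 + confidence / 2, df)
    c = fit.param_covariance
    s2 = fit.residual_sd ** 2
    if method == "delta":
        # Var(kb_hat) ~ [s^2 + Var(b0) + kb^2 Var(b1) + 2 kb Cov(b0,b1)] / b1^2
        var = (s2 + c[0, 0] + kb * kb * c[1, 1] + 2 * kb * c[0, 1]) / fit.slope ** 2
        half = tcrit * float(np.sqrt(max(var, 0.0)))
        lo, hi = kb - half, kb + half
    elif method == "fieller":
        lo, hi = _fieller_interval(fit, y0, tcrit)
    else:
        raise ValueError(f"unknown interval method {method!r}")
    flags = frozenset({"negative-kb"}) if kb < 0 else frozenset()
    return DnaEstimate(kb=float(kb), ci_low=float(lo), ci_high=float(hi),
                       net_intensity=y0, method=method, flags=flags)


def _fieller_interval(fit: CalibrationFit, y0: float, tcrit: float) -> tuple[float, float]:
    """Fieller bounds: roots in x of (y0 - b0 - b1 x)^2 = t^2 Var(y0 - b0 - b1 x)."""
    b0, b1 = fit.intercept, fit.slope
    c = fit.param_covariance
    s2 = fit.residual_sd ** 2
    t2 = tcrit ** 2
    A = b1 ** 2 - t2 * c[1, 1]
    B = -2 * b1 * (y0 - b0) + 2 * t2 * c[0, 1]
    C = (y0 - b0) ** 2 - t2 * (s2 + c[0, 0])
    if A <= 0:
        return -np.inf, np.inf  # slope not significant: unbounded interval
    disc = B * B - 4 * A * C
    if disc < 0:
        return -np.inf, np.inf
    r = np.sqrt(disc)
    return (-B - r) / (2 * A), (-B + r) / (2 * A)


def fit_diagnostics(fit: CalibrationFit) -> pd.DataFrame:
    """Residuals, leverage and studentized residuals per standard point.

    Outliers are flagged on the externally studentized (leave-one-out)
    residual exceeding 3 in magnitude; the internally standardized residual
    is bounded by (n-1)/sqrt(n) and cannot reach 3 for small standard sets.
    """
    if not fit.points:
        raise ValueError("fit carries no points to diagnose")
    kb = np.array([p.genome_kb for p in fit.points], dtype=float)
    y = np.array([p.net_intensity for p in fit.points], dtype=float)
    resid = y - fit.predict_intensity(kb)
    n = len(kb)
    sxx = float(((kb - kb.mean()) ** 2).sum())
    leverage = 1.0 / n + (kb - kb.mean()) ** 2 / sxx
    scale = max(float(np.abs(y).mean()), 1.0)
    if fit.residual_sd <= 1e-10 * scale:  # perfect fit: residuals are noise-free
        zeros = np.zeros(n)
        std_resid = student = zeros
    else:
        denom = fit.residual_sd * np.sqrt(np.clip(1.0 - leverage, 1e-12, None))
        std_resid = resid / denom
        df = n - 2
        # externally studentized: t_i = r_i sqrt((df-1)/(df - r_i^2))
        inner = np.clip(df - std_resid ** 2, 1e-12, None)
        student = std_resid * np.sqrt((df - 1) / inner)
    return pd.DataFrame({
        "spot_id": [p.spot_id for p in fit.points],
        "genome_kb": kb,
        "net_intensity": y,
        "residual": resid,
        "leverage": leverage,
        "std_residual": std_resid,
        "studentized_residual": student,
        "outlier": np.abs(student) > 3,
    })
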