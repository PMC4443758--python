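"""Population-level fits and statistics.

Calcium cooperativity: at the fly NMJ release scales with external calcium
as a power law, QC = k * [Ca]^n with n ~ 3; the exponent is the slope of an
OLS line on (log Ca, log QC).

Homeostasis curve: across perturbations of quantal size, quantal content
scales so that the evoked EPSP holds a set-point.  Perfect compensation
implies the one-parameter reciprocal model QC = E0 / mEPSP; the descriptive
two-parameter exponential QC = a * exp(b * mEPSP) is also provided.

Group comparisons use a two-sample, two-sided Student's t-test
(pooled-variance by default, Welch by flag), errors are reported as SEM, and
no multiple-testing correction is applied anywhere — raw p-values only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats as sps

from .errors import ParameterError

__all__ = [
    "CooperativityFit",
    "HomeostasisFit",
    "GroupComparison",
    "cooperativity_fit",
    "homeostasis_curve_fit",
    "predicted_release_change",
    "group_compare",
]


@dataclass
class CooperativityFit:
    """log-log power-law fit of quantal content against external calcium."""

    exponent: float
    log_k: float
    r_squared: float
    n_points: int

    def summary(self) -> str:
        r2 = f"{self.r_squared:.4f}" if np.isfinite(self.r_squared) else "n/a"
        return (f"Calcium cooperativity: QC = k * Ca^{self.exponent:.3f} "
                f"(log k = {self.log_k:.3f}, R^2 = {r2}, n = {self.n_points})")


@dataclass
class HomeostasisFit:
    """Fit of quantal content against quantal size under a set-point."""

    model: str                               # "reciprocal_setpoint" | "exponential"
    params: dict[str, float]
    r_squared: float
    predicted_epsp_by_point: list[float]
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        pars = ", ".join(f"{k} = {v:.4g}" for k, v in self.params.items())
        return f"Homeostasis fit [{self.model}]: {pars}, R^2 = {self.r_squared:.4f}"


@dataclass
class GroupComparison:
    """Two-group comparison: means, SEMs and Student's t-test."""

    group_means: tuple[float, float]
    sems: tuple[float, float]
    t_stat: float
    p_value: float
    n: tuple[int, int]
    welch: bool = False

    def summary(self) -> str:
        return (f"group A: {self.group_means[0]:.4g} +/- {self.sems[0]:.3g} (n={self.n[0]}), "
                f"group B: {self.group_means[1]:.4g} +/- {self.sems[1]:.3g} (n={self.n[1]}); "
                f"t = {self.t_stat:.3f}, p = {self.p_value:.4g}"
                + (" (Welch)" if self.welch else ""))


def cooperativity_fit(points: Sequence[tuple[float, float]]) -> CooperativityFit:
    """OLS line on (log Ca, log QC); the slope is the cooperativity exponent.

    Requires >= 2 strictly positive points; R^2 is reported only for >= 3.
    Rescaling all QC values by a constant changes only the intercept.
    """
    pts = [(float(ca), float(qc)) for ca, qc in points]
    if len(pts) < 2:
        raise ParameterError("need at least 2 points")
    if any(ca <= 0 or qc <= 0 for ca, qc in pts):
        raise ParameterError("all calcium and quantal-content values must be > 0")
    x = np.log([ca for ca, _ in pts])
    y = np.log([qc for _, qc in pts])
    res = sps.linregress(x, y)
    r2 = float(res.rvalue ** 2) if len(pts) >= 3 else float("nan")
    return CooperativityFit(float(res.slope), float(res.intercept), r2, len(pts))


def _r_squared(y: np.ndarray, y_fit: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_fit) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def homeostasis_curve_fit(points: Sequence[tuple[float, float]],
                          model: str = "reciprocal_setpoint") -> HomeostasisFit:
    """Fit quantal content as a function of mEPSP amplitude.

    ``reciprocal_setpoint``: QC = E0 / mEPSP, the single-parameter model a
    perfect EPSP set-point implies; E0 has a closed-form least-squares
    solution.  ``exponential``: QC = a * exp(b * mEPSP), the descriptive
    two-parameter alternative.  Either way the per-point predicted EPSP is
    QC_fit * mEPSP (constant at E0 for the reciprocal model).
    """
    pts = [(float(m), float(qc)) for m, qc in points]
    if len(pts) < 3:
        raise ParameterError("need at least 3 points")
    if any(m <= 0 or qc <= 0 for m, qc in pts):
        raise ParameterError("all mEPSP and quantal-content values must be > 0")
    m = np.array([p[0] for p in pts])
    qc = np.array([p[1] for p in pts])

    if model == "reciprocal_setpoint":
        e0 = float(np.sum(qc / m) / np.sum(1.0 / m ** 2))
        qc_fit = e0 / m
        return HomeostasisFit(model, {"setpoint_mV": e0}, _r_squared(qc, qc_fit),
                              list(qc_fit * m))
    if model == "exponential":
        # log-linear start values, then full nonlinear least squares
        b0, loga0 = np.polyfit(m, np.log(qc), 1)
        try:
            popt, _ = optimize.curve_fit(lambda x, a, b: a * np.exp(b * x),
                                         m, qc, p0=[math.exp(loga0), b0], maxfev=20000)
        except (RuntimeError, ValueError):
            return HomeostasisFit(model, {}, float("nan"), [], flags=["fit_failed"])
        a, b = (float(v) for v in popt)
        qc_fit = a * np.exp(b * m)
        return HomeostasisFit(model, {"a": a, "b": b}, _r_squared(qc, qc_fit),
                              list(qc_fit * m))
    raise ParameterError(f"unknown model {model!r}")


def predicted_release_change(ca_fraction: float, exponent: float) -> float:
    """Percent decrease in release predicted by the power law.

    For a calcium signal reduced to ``ca_fraction`` of control, release falls
    to ``ca_fraction ** exponent``; the return value is
    ``100 * (1 - ca_fraction ** exponent)``.  Monotone decreasing in
    ``ca_fraction`` and increasing in ``exponent``.
    """
    if not (0 < ca_fraction <= 1):
        raise ParameterError("ca_fraction must lie in (0, 1]")
    if exponent <= 0:
        raise ParameterError("exponent must be > 0")
    return 100.0 * (1.0 - ca_fraction ** exponent)


def group_compare(a: Sequence[float], b: Sequence[float],
                  *, welch: bool = False) -> GroupComparison:
    """Two-sample two-sided t-test with group means and SEMs.

    Pooled-variance Student's test by default; ``welch=True`` drops the
    equal-variance assumption.  Symmetric under group swap.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    sem = lambda x: float(np.std(x, ddof=1) / math.sqrt(x.size))
    return GroupComparison((float(np.mean(a)), float(np.mean(b))),
                           (sem(a), sem(b)),
                           float(res.statistic), float(res.pvalue),
                           (a.size, b.size), welch=welch)
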