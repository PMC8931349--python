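"""Initial contact-point estimation on the tip-sample separation axis.

The approach segment is modelled piecewise around a candidate contact point:
a linear baseline ``F = m*delta + d`` before contact (delta < 0) and a
rational indentation branch

    F = delta^3 / (a*delta^2 + b*delta + c) + m*delta + d     (delta > 0)

after it.  For small indentations the branch behaves as ``delta^3/c`` (flat,
slightly cubic) and for large indentations as ``(1/a + m)*delta`` (linear),
which brackets the curvature of sphere-indentation data without committing
to a material model.  The candidate minimising the residual sum of squares
over an exhaustive scan of sample positions is returned.

The baseline parameters (m, d) are always fitted on the pre-contact data
alone and held fixed while the branch is fitted, so the baseline estimate is
never distorted by branch-model mismatch.  Because the cubic-onset branch
rises more slowly than the delta^(3/2) of sphere contact, the sse-minimising
candidate sits systematically a few percent of the indentation depth *early*
on such data; the estimate is therefore explicitly an initial guess, and the
viscoelastic fit re-optimises the contact point jointly with the material
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, nnls

from .curves import ForceCurve, tip_sample_separation

__all__ = ["ContactPointFit", "NoContactError", "estimate_contact_point"]

_MIN_BRANCH = 4          # samples required on each side of a candidate
_NOISE_MULT = 8.0        # contact detection threshold in units of baseline noise


class NoContactError(RuntimeError):
    """The curve never leaves the baseline: no indentation branch to fit."""


@dataclass
class ContactPointFit:
    """Piecewise line+polynomial contact-point fit."""

    cp: float          # contact position on the separation axis [m]
    m: float           # baseline slope [N/m]
    d: float           # baseline force offset [N]
    a: float           # rational-branch coefficients; F ~ delta^3/c small-delta,
    b: float           # F ~ (1/a + m)*delta large-delta
    c: float
    sse: float         # residual sum of squares [N^2]
    index: int         # sample index of cp within the approach segment
    scan_step: float   # median separation-axis sample spacing [m]

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("polynomial coefficient c must be positive")
        if self.sse < 0:
            raise ValueError("sse must be non-negative")

    def model(self, delta: np.ndarray) -> np.ndarray:
        """Evaluate the piecewise model at indentations measured from cp."""
        delta = np.asarray(delta, float)
        base = self.m * delta + self.d
        pos = delta > 0
        out = base.copy()
        dp = delta[pos]
        out[pos] = dp**3 / (self.a * dp**2 + self.b * dp + self.c) + base[pos]
        return out


def _baseline_noise(F: np.ndarray) -> float:
    """Noise scale from the detrended first quarter of the segment."""
    head = F[: max(len(F) // 4, 8)]
    x = np.arange(len(head), dtype=float)
    coef = np.polyfit(x, head, 1)
    return float(np.std(head - np.polyval(coef, x)))


def _candidate_sse(s: np.ndarray, F: np.ndarray, j: int) -> tuple[float, np.ndarray]:
    """Piecewise fit with cp frozen at sample j; returns (sse, (m,d,a,b,c)).

    Expects dimensionless (scaled) s and F.  The baseline is a plain linear
    least squares on delta < 0; the rational branch is linearised as
    ``(a d^2 + b d + c) g = d^3`` with ``g`` the baseline-subtracted force
    and solved under non-negativity (keeps the denominator pole-free).
    """
    delta = s - s[j]
    neg, pos = delta < 0, delta > 0
    if neg.sum() < _MIN_BRANCH or pos.sum() < _MIN_BRANCH:
        return np.inf, np.zeros(5)
    A = np.column_stack([delta[neg], np.ones(neg.sum())])
    (m, d), *_ = np.linalg.lstsq(A, F[neg], rcond=None)
    dp = delta[pos]
    g = F[pos] - m * dp - d
    B = np.column_stack([dp**2 * g, dp * g, g])
    try:
        (a, b, c), _ = nnls(B, dp**3)
    except (np.linalg.LinAlgError, RuntimeError):
        return np.inf, np.zeros(5)
    den = a * dp**2 + b * dp + c
    if np.any(den <= 0):  # all-zero solution: branch cannot be represented
        return np.inf, np.zeros(5)
    resid = np.concatenate([A @ [m, d] - F[neg], dp**3 / den + m * dp + d - F[pos]])
    return float(resid @ resid), np.array([m, d, a, b, c])


_ABC_FLOOR = 1e-12  # scaled units; log-parametrised branch coefficients


def _polish_abc(s: np.ndarray, F: np.ndarray, j: int, p: np.ndarray) -> tuple[float, np.ndarray]:
    """Refine (a, b, c) in log space with the baseline (m, d) held fixed."""
    delta = s - s[j]
    neg, pos = delta < 0, delta > 0
    m, d = p[0], p[1]
    dp = delta[pos]
    g = F[pos] - m * dp - d
    sse_base = float(np.sum((m * delta[neg] + d - F[neg]) ** 2))

    def resid(theta):
        a, b, c = np.exp(np.clip(theta, -60.0, 60.0))
        return dp**3 / (a * dp**2 + b * dp + c) - g

    theta0 = np.log(np.maximum(p[2:5], _ABC_FLOOR))
    sol = least_squares(resid, theta0, method="lm", max_nfev=400)
    return sse_base + float(sol.fun @ sol.fun), np.exp(np.clip(sol.x, -60.0, 60.0))


def estimate_contact_point(
    approach: ForceCurve,
    *,
    scan_fraction: float = 0.8,
    noise_multiplier: float = _NOISE_MULT,
) -> ContactPointFit:
    """Exhaustive-scan line+polynomial contact-point estimate.

    Every sample index within the central ``scan_fraction`` of the approach
    segment is tried as the contact point; ties break toward the smallest
    separation.  Raises :class:`NoContactError` when the force never rises
    above the baseline by more than ``noise_multiplier`` times the baseline
    noise (and a machine-precision floor, so noiseless flat baselines are
    also rejected).
    """
    s_raw = tip_sample_separation(approach)
    F_raw = approach.F
    n = len(s_raw)

    sigma = _baseline_noise(F_raw)
    x0 = np.arange(n, dtype=float)
    coef = np.polyfit(x0[: n // 2], F_raw[: n // 2], 1)
    excess = F_raw - np.polyval(coef, x0)
    F_span = float(np.max(np.abs(F_raw)))
    floor = 1e-6 * max(F_span, 1e-30) + 1e-18
    if np.max(excess) < max(noise_multiplier * sigma, floor):
        raise NoContactError("force never rises above the baseline: no contact")

    # dimensionless coordinates: keeps the branch solve well conditioned
    D = float(s_raw.max() - s_raw.min())
    F_s = max(F_span, 1e-30)
    s = (s_raw - s_raw.min()) / D
    F = F_raw / F_s

    lo = int(np.floor(n * (1 - scan_fraction) / 2))
    hi = int(np.ceil(n * (1 + scan_fraction) / 2))
    # cap the scan at ~600 candidates: beyond that the grid is far finer
    # than the estimator's own uncertainty and only burns time
    stride = max(1, (hi - lo) // 600)
    best: tuple[float, int, np.ndarray] | None = None
    for j in range(lo, hi, stride):
        sse, p = _candidate_sse(s, F, j)
        if np.isfinite(sse) and (best is None or sse < best[0]):
            best = (sse, j, p)
    if best is None:
        raise NoContactError("no candidate admits a valid piecewise fit")

    sse, j, p = best
    sse, abc = _polish_abc(s, F, j, p)

    step = stride * float(np.median(np.abs(np.diff(s_raw))))
    # convert back to SI: F = F_s * f(delta / D)
    m = p[0] * F_s / D
    d = p[1] * F_s
    a = abc[0] * D / F_s
    b = abc[1] * D**2 / F_s
    c = abc[2] * D**3 / F_s
    return ContactPointFit(cp=float(s_raw[j]), m=m, d=d, a=a, b=b, c=c,
                           sse=sse * F_s**2, index=j, scan_step=step)
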