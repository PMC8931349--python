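"""Kelvin-Voigt-Maxwell curve fitting: Model / Results objects.

:class:`KVMModel` is built from one force curve plus probe geometry; its
:meth:`~KVMModel.fit` minimises the squared force residual of the explicit
KVM force-indentation relation over (E0, E1, lam, eta, cp) with a
Nelder-Mead simplex (lmfit, which imposes the box bounds through an internal
smooth parameter transform).  The Poisson ratio is held fixed (0.5 for
incompressible soft matter).  The Maxwell relaxation time is confined to
[t_ind/5, 10*t_ind]: outside that box its effect on an approach of duration
t_ind is not identifiable, and the fit instead reports the robust derived
moduli Eu = E0+E1 and Eapp (boundary saturation is flagged, never hidden).

Geometric corrections for rounded cells (effective radius, confinement
factor) and the finite-thickness ("bottom effect") force-overestimation
diagnostic live here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
from scipy.optimize import brentq, nnls

from . import __version__ as _version
from .contact import ContactPointFit, estimate_contact_point
from .curves import ForceCurve, split_segments, tip_sample_separation
from .models import (
    CalibrationConstants,
    DerivedModuli,
    ProbeGeometry,
    ViscoelasticParams,
    derived_moduli,
    ding_force,
    kvm_force,
)

__all__ = [
    "FitConfig",
    "KVMModel",
    "KVMResults",
    "fit_kvm_curve",
    "effective_radius",
    "confinement_factor",
    "confinement_correction",
    "BottomEffect",
    "bottom_effect_estimate",
    "indentation_for_semiinfinite_force",
    "write_results",
]

# internal fit units: kPa, s, Pa.s, um — keeps simplex coordinates O(1)
_KPA = 1e3
_UM = 1e-6


@dataclass
class FitConfig:
    """Tunables of the KVM curve fit; defaults match routine practice."""

    nu: float = 0.5
    lam_bounds: tuple[float, float] = (0.2, 10.0)  # multipliers of t_ind
    cp_window_frac: float = 0.12        # cp refit window, fraction of depth
    max_nfev: int = 20000
    xatol: float = 1e-6                 # simplex tolerance (scaled units)
    fatol: float = 1e-12                # simplex tolerance on scaled SSE
    boundary_tol: float = 0.01          # flag params within 1% of their box
    restarts: int = 0                   # extra perturbed starts
    restart_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lam_bounds
        if not (0 < lo < hi):
            raise ValueError("lam bounds must satisfy 0 < lower < upper")
        if self.xatol <= 0 or self.fatol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class KVMResults:
    """Fitted KVM parameters, contact point, derived moduli and diagnostics."""

    params: ViscoelasticParams
    cp: float                    # refit contact position on separation axis [m]
    delta_max: float             # maximum (corrected) indentation [m]
    t_ind: float                 # indentation time delta_max / v [s]
    derived: DerivedModuli
    sse: float                   # residual sum of squares [N^2]
    rms: float                   # root-mean-square force residual [N]
    flags: dict[str, bool]
    contact_fit: ContactPointFit
    nfev: int
    success: bool
    model: "KVMModel" = field(repr=False)

    def fitted_force(self) -> np.ndarray:
        """Model force (baseline-referenced) at the fitted parameters."""
        return self.model._model_force(self.params, self.cp)

    def residuals(self) -> np.ndarray:
        return self.model._F_fit - self.fitted_force()

    def summary(self) -> str:
        p, d = self.params, self.derived
        lines = [
            "KVM force-indentation fit",
            "=" * 44,
            f"{'E0 (Kelvin-Voigt modulus)':32s} {p.E0 / _KPA:10.4f} kPa",
            f"{'E1 (Maxwell modulus)':32s} {p.E1 / _KPA:10.4f} kPa",
            f"{'lambda (relaxation time)':32s} {p.lam:10.4f} s",
            f"{'eta (apparent viscosity)':32s} {p.eta:10.4f} Pa s",
            f"{'Eu = E0 + E1 (unrelaxed)':32s} {d.Eu / _KPA:10.4f} kPa",
            f"{'Eapp (apparent, at t_ind)':32s} {d.Eapp / _KPA:10.4f} kPa",
            "-" * 44,
            f"{'contact point':32s} {self.cp / _UM:10.4f} um",
            f"{'max indentation':32s} {self.delta_max / _UM:10.4f} um",
            f"{'indentation time t_ind':32s} {self.t_ind:10.4f} s",
            f"{'rms force residual':32s} {self.rms * 1e9:10.4f} nN",
            f"{'function evaluations':32s} {self.nfev:10d}",
        ]
        raised = [k for k, v in self.flags.items() if v]
        lines.append(f"{'flags':32s} {', '.join(raised) if raised else 'none':>10s}")
        return "\n".join(lines)

    def to_row(self) -> dict:
        meta = self.model.curve.meta
        return {
            "curve_id": meta.curve_id, "group": meta.group, "cell_id": meta.cell_id,
            "E0_Pa": self.params.E0, "E1_Pa": self.params.E1,
            "lambda_s": self.params.lam, "eta_Pa_s": self.params.eta,
            "Eu_Pa": self.derived.Eu, "Eapp_Pa": self.derived.Eapp,
            "cp_m": self.cp, "delta_max_m": self.delta_max, "t_ind_s": self.t_ind,
            "sse": self.sse,
            "flags": ";".join(k for k, v in self.flags.items() if v),
        }


class KVMModel:
    """Explicit KVM force-indentation model bound to one approach curve.

    Parameters
    ----------
    curve : ForceCurve
        Full cycle or approach-only curve; only the approach is fitted.
    geom : ProbeGeometry, optional
        Falls back to the curve metadata (radius, cell radius, thickness).
    config : FitConfig, optional
    constants : CalibrationConstants, optional
        The fixed alpha1..alpha4 of the explicit relation.

    Notes
    -----
    Construction performs the full preprocessing chain: segment split,
    tip-sample separation correction, initial line+polynomial contact-point
    estimate, baseline subtraction and force-setpoint trimming.  ``fit()``
    then re-optimises the contact point jointly with the material state.
    """

    def __init__(
        self,
        curve: ForceCurve,
        geom: ProbeGeometry | None = None,
        config: FitConfig | None = None,
        constants: CalibrationConstants | None = None,
    ) -> None:
        self.curve = curve
        self.config = config or FitConfig()
        self.constants = constants or CalibrationConstants()
        if geom is None:
            if curve.meta.radius is None:
                raise ValueError("probe radius needed: pass geom or set metadata")
            geom = ProbeGeometry(
                R=curve.meta.radius, Rcell=curve.meta.cell_radius,
                h=curve.meta.thickness,
            )
        self.geom = geom

        approach, _ = split_segments(curve)
        self.approach = approach
        self._s = tip_sample_separation(approach)
        self.contact0 = estimate_contact_point(approach)

        v = curve.meta.velocity
        if v is None:
            v = float(np.median(np.abs(np.gradient(self._s, approach.t))))
        if v <= 0:
            raise ValueError("approach velocity must be positive")
        self.v = v

        # baseline referenced to the initial contact estimate
        c0 = self.contact0
        baseline = c0.m * (self._s - c0.cp) + c0.d
        F_corr = approach.F - baseline
        keep = np.ones(len(F_corr), dtype=bool)
        if curve.meta.setpoint is not None:
            keep = F_corr <= curve.meta.setpoint  # drop instrument overshoot
        self._keep = keep
        self._s_fit = self._s[keep]
        self._F_fit = F_corr[keep]

        self._K = self.geom.K          # None for flat samples
        self._R_fit = self.geom.Reff   # == R when no cell radius

    # -- model evaluation ------------------------------------------------

    def _indentation(self, cp: float) -> np.ndarray:
        delta = self._s_fit - cp
        if self._K is not None:
            delta = np.where(delta > 0, self._K * delta, delta)
        return delta

    def _model_force(self, p: ViscoelasticParams, cp: float) -> np.ndarray:
        return kvm_force(p, self.constants, self._R_fit, self.v, self._indentation(cp),
                         clip=True)

    # -- initial values --------------------------------------------------

    def _initial_params(self, t_ind: float) -> tuple[float, float, float, float]:
        """(E0, E1, lam, eta) fallback start: Ding fit on the deep half."""
        cfg = self.config
        delta = self._indentation(self.contact0.cp)
        dmax = float(np.max(delta))
        deep = delta > 0.5 * dmax
        shape = ding_force(1.0, cfg.nu, self._R_fit, delta[deep], clip=True)
        denom = float(shape @ shape)
        E_all = float(shape @ self._F_fit[deep]) / denom if denom > 0 else 1e3
        E_all = max(E_all, 1.0)
        E0_0, E1_0 = (2 / 3) * E_all, (1 / 3) * E_all
        shallow = (delta > 0) & (delta < 0.3 * dmax)
        eta_0 = 0.01
        if shallow.sum() >= 3:
            mismatch = self._F_fit[shallow] - ding_force(
                E_all, cfg.nu, self._R_fit, delta[shallow], clip=True
            )
            scale = (self.constants.alpha2 * np.sqrt(self._R_fit * delta[shallow])
                     * self.v)
            eta_0 = float(np.median(mismatch / scale))
        eta_0 = min(max(eta_0, 1e-3), 1e4)
        return E0_0, E1_0, t_ind, eta_0

    def _grid_start(self, cp0: float, window: float, t_ind: float):
        """Profile the sse over a (lam, cp) grid, solving (E0, E1, eta) by NNLS.

        The model is linear in the moduli and the viscosity once lam and cp
        are fixed, so an exhaustive coarse grid locates the global basin —
        in particular it separates the true contact point from the slightly
        early line+polynomial estimate, whose spurious pre-contact force the
        viscous sqrt(delta) onset could otherwise be traded against.
        """
        cfg = self.config
        lam_lo, lam_hi = cfg.lam_bounds[0] * t_ind, cfg.lam_bounds[1] * t_ind
        cp_grid = cp0 + np.linspace(-0.3 * window, window, 16)
        lam_grid = np.geomspace(lam_lo * 1.05, lam_hi * 0.95, 7)
        a1, a2 = self.constants.alpha1, self.constants.alpha2
        cands: list[tuple[float, np.ndarray, float, float]] = []
        for cp in cp_grid:
            delta = self._indentation(cp)
            pos = np.clip(delta, 0.0, None)
            phi0 = ding_force(1.0, cfg.nu, self._R_fit, pos, clip=True)
            phi2 = a2 * np.sqrt(self._R_fit * pos) * self.v
            best_cp = None
            for lam in lam_grid:
                phi1 = phi0 * np.exp(-a1 * pos / (self.v * lam))
                A = np.column_stack([phi0, phi1, phi2])
                try:
                    coef, _ = nnls(A, self._F_fit)
                except RuntimeError:
                    continue
                r = A @ coef - self._F_fit
                sse = float(r @ r)
                if best_cp is None or sse < best_cp[0]:
                    best_cp = (sse, coef, lam, cp)
            if best_cp is not None:
                cands.append(best_cp)
        if not cands:
            return [(*self._initial_params(t_ind), cp0)]
        cands.sort(key=lambda c: c[0])
        # top candidate plus the best one at a distinctly different cp:
        # the sse valley in cp can be double-welled (contact onset vs the
        # viscous sqrt(delta) rise), so both basins get a full refinement
        starts = [cands[0]]
        for c in cands[1:]:
            if abs(c[3] - cands[0][3]) > 0.15 * window:
                starts.append(c)
                break
        return [(max(e0, 1.0), max(e1, 1.0), lam,
                 min(max(eta, 1e-3), 1e4), cp)
                for _, (e0, e1, eta), lam, cp in starts]

    # -- fitting ---------------------------------------------------------

    def fit(self) -> KVMResults:
        cfg = self.config
        cp0 = self.contact0.cp
        # window sized by indentation depth, not sample spacing: it must
        # cover the initial estimator's early bias yet exclude the baseline
        window = cfg.cp_window_frac * float(np.max(self._s_fit) - cp0)

        t_ind = float(np.max(self._indentation(cp0))) / self.v
        out = None
        for start in self._grid_start(cp0, window, t_ind):
            trial = self._minimize(start[:4], cp0, window, t_ind, cp_start=start[4])
            if out is None or trial.chisqr < out.chisqr:
                out = trial

        # lam box depends on t_ind which depends on the refit cp: one more
        # pass when the contact point moved enough to change the box
        cp1 = out.params["cp"].value * _UM
        t_ind1 = float(np.max(self._s_fit - cp1)) * (self._K or 1.0) / self.v
        if abs(t_ind1 - t_ind) > 0.01 * t_ind:
            start1 = (out.params["E0"].value * _KPA, out.params["E1"].value * _KPA,
                      min(max(out.params["lam"].value, cfg.lam_bounds[0] * t_ind1),
                          cfg.lam_bounds[1] * t_ind1),
                      out.params["eta"].value)
            out = self._minimize(start1, cp0, window, t_ind1, cp_start=cp1)
            t_ind = t_ind1

        vals = out.params.valuesdict()
        lam_lo, lam_hi = cfg.lam_bounds[0] * t_ind, cfg.lam_bounds[1] * t_ind
        p = ViscoelasticParams(
            E0=max(vals["E0"], 0.0) * _KPA, E1=max(vals["E1"], 0.0) * _KPA,
            lam=min(max(vals["lam"], lam_lo), lam_hi),
            eta=max(vals["eta"], 0.0), nu=cfg.nu,
        )
        cp = vals["cp"] * _UM
        delta_max = float(np.max(self._indentation(cp)))
        t_ind_final = delta_max / self.v
        resid = self._F_fit - self._model_force(p, cp)
        sse = float(resid @ resid)
        span = lam_hi - lam_lo
        # a relaxation time is "at" a box edge either when the estimate sits
        # there or when pinning it there fits the data essentially as well
        # (the profile in lam is flat: the classic lam/t_ind degeneracy)
        at_hi = (lam_hi - p.lam) < cfg.boundary_tol * span
        at_lo = (p.lam - lam_lo) < cfg.boundary_tol * span
        signal = float(self._F_fit @ self._F_fit)
        # pinning lam at the edge must worsen the fit by more than a
        # chi-square-scale increment (4*sse/n ~ 95% LR for one parameter);
        # the absolute floor covers noise-free curves where sse ~ 0
        crit = max(4.0 * sse / max(len(resid), 1), 1e-8 * signal)
        if not at_hi:
            at_hi = self._profile_sse(lam_hi, cp) - sse <= crit
        if not at_lo:
            at_lo = self._profile_sse(lam_lo, cp) - sse <= crit
        flags = {
            "lam_at_upper_bound": p.E1 > 0 and at_hi,
            "lam_at_lower_bound": p.E1 > 0 and at_lo,
            "E1_at_zero": p.E1 <= 1e-3 * max(p.E0, 1.0),
            "no_contact": False,
            "not_converged": not out.success,
        }
        return KVMResults(
            params=p, cp=cp, delta_max=delta_max, t_ind=t_ind_final,
            derived=derived_moduli(p, self.constants, delta_max, self.v),
            sse=sse, rms=math.sqrt(sse / len(resid)), flags=flags,
            contact_fit=self.contact0, nfev=int(out.nfev),
            success=bool(out.success), model=self,
        )

    def _profile_sse(self, lam: float, cp: float) -> float:
        """Best sse with lam and cp pinned: (E0, E1, eta) re-fit by NNLS."""
        cfg = self.config
        delta = self._indentation(cp)
        pos = np.clip(delta, 0.0, None)
        phi0 = ding_force(1.0, cfg.nu, self._R_fit, pos, clip=True)
        phi1 = phi0 * np.exp(-self.constants.alpha1 * pos / (self.v * lam))
        phi2 = self.constants.alpha2 * np.sqrt(self._R_fit * pos) * self.v
        A = np.column_stack([phi0, phi1, phi2])
        try:
            coef, _ = nnls(A, self._F_fit)
        except RuntimeError:
            return np.inf
        r = A @ coef - self._F_fit
        return float(r @ r)

    def _minimize(self, start, cp0, window, t_ind, cp_start=None):
        cfg = self.config
        E0_0, E1_0, lam_0, eta_0 = start
        lam_lo, lam_hi = cfg.lam_bounds[0] * t_ind, cfg.lam_bounds[1] * t_ind
        lam_0 = min(max(lam_0, lam_lo * 1.01), lam_hi * 0.99)

        F_scale = max(float(np.max(np.abs(self._F_fit))), 1e-30)

        def residual(params):
            p = ViscoelasticParams(
                E0=params["E0"].value * _KPA, E1=params["E1"].value * _KPA,
                lam=params["lam"].value, eta=params["eta"].value, nu=cfg.nu,
            )
            return (self._model_force(p, params["cp"].value * _UM) - self._F_fit) / F_scale

        def make_params(e0, e1, lam, eta, cp):
            pars = lmfit.Parameters()
            pars.add("E0", value=e0 / _KPA, min=0.0)
            pars.add("E1", value=e1 / _KPA, min=0.0)
            pars.add("lam", value=lam, min=lam_lo, max=lam_hi)
            pars.add("eta", value=eta, min=0.0)
            pars.add("cp", value=cp / _UM, min=(cp0 - window) / _UM,
                     max=(cp0 + window) / _UM)
            return pars

        options = {"maxfev": cfg.max_nfev, "xatol": cfg.xatol,
                   "fatol": cfg.fatol, "adaptive": True}

        def run(pars):
            # simplex global search (stable for the exponent), then a
            # trust-region polish to drive the local minimum to tolerance
            out = lmfit.minimize(residual, pars, method="nelder", options=options)
            polished = lmfit.minimize(residual, out.params, method="least_squares")
            return polished if polished.chisqr <= out.chisqr else out

        if cp_start is None:
            cp_start = cp0
        cp_start = min(max(cp_start, cp0 - window * 0.999), cp0 + window * 0.999)
        best = run(make_params(E0_0, E1_0, lam_0, eta_0, cp_start))
        if cfg.restarts:
            rng = np.random.default_rng(cfg.restart_seed)
            for _ in range(cfg.restarts):
                f = rng.lognormal(0.0, 0.3, size=4)
                pars = make_params(E0_0 * f[0], E1_0 * f[1],
                                   min(max(lam_0 * f[2], lam_lo * 1.01), lam_hi * 0.99),
                                   eta_0 * f[3], cp_start)
                trial = run(pars)
                if trial.chisqr < best.chisqr:
                    best = trial
        return best


def fit_kvm_curve(
    approach: ForceCurve,
    geom: ProbeGeometry | None = None,
    cfg: FitConfig | None = None,
    constants: CalibrationConstants | None = None,
) -> KVMResults:
    """One-call convenience wrapper: build a :class:`KVMModel` and fit it."""
    return KVMModel(approach, geom, cfg, constants).fit()


# -- geometric corrections ------------------------------------------------

def effective_radius(Rcell: float, Rbead: float) -> float:
    """Series-contact effective radius 1/Reff = 1/Rcell + 1/Rbead."""
    if Rcell <= 0 or Rbead <= 0:
        raise ValueError("radii must be positive")
    return 1.0 / (1.0 / Rcell + 1.0 / Rbead)


def confinement_factor(Rcell: float, Reff: float) -> float:
    """K = Rcell^(1/3) / (Rcell^(1/3) + Reff^(1/3)).

    Correction for the extra flattening a rounded cell confined between
    probe and dish experiences; the measured indentation overstates the
    contact indentation by 1/K.
    """
    if Rcell <= 0 or Reff < 0:
        raise ValueError("Rcell must be positive and Reff non-negative")
    a, b = Rcell ** (1 / 3), Reff ** (1 / 3)
    return a / (a + b)


def confinement_correction(delta_measured, Rcell: float, Reff: float):
    """Scaled indentation K * delta_measured for rounded-cell curves."""
    return confinement_factor(Rcell, Reff) * np.asarray(delta_measured, float)


# -- bottom-effect diagnostic ---------------------------------------------

@dataclass(frozen=True)
class BottomEffect:
    """Two-term finite-thickness force series and the neglected fraction."""

    F0: float               # semi-infinite (half-space) term [N]
    F1: float               # first finite-thickness correction [N]
    overestimation: float   # F1 / F0


def bottom_effect_estimate(
    Eapp: float, eta: float, R: float, h: float, v: float, I: float,
) -> BottomEffect:
    """Estimate the force over-estimation from neglecting finite thickness.

    For a viscoelastic layer of thickness ``h`` on a rigid support, with the
    simplified relaxation function ``phi = Eapp + eta*dirac(t)`` and constant
    indentation rate ``v``, the first two terms of the layer series are

        F0 = (16/9) sqrt(R I) [ (9/2) eta v + Eapp I ]
        F1 = 1.133 (16/9) (R I / h) [ 6 eta v + Eapp I ]

    and the half-space analysis overestimates the force by ``F1/F0`` (terms
    of order I^(3/2)/h^2 and higher are truncated).  This is a reporting
    diagnostic only; the fitted model itself neglects the substrate.
    """
    if h <= 0:
        raise ValueError("sample thickness h must be positive")
    if I < 0 or R <= 0:
        raise ValueError("indentation must be >= 0 and R > 0")
    F0 = (16.0 / 9.0) * math.sqrt(R * I) * (4.5 * eta * v + Eapp * I)
    F1 = 1.133 * (16.0 / 9.0) * (R * I / h) * (6.0 * eta * v + Eapp * I)
    return BottomEffect(F0=F0, F1=F1, overestimation=F1 / F0 if F0 > 0 else 0.0)


def indentation_for_semiinfinite_force(
    F_target: float, Eapp: float, eta: float, R: float, v: float,
) -> float:
    """Indentation at which the semi-infinite term F0 reaches ``F_target``."""
    if F_target <= 0:
        raise ValueError("target force must be positive")

    def f(I):
        return (16.0 / 9.0) * math.sqrt(R * I) * (4.5 * eta * v + Eapp * I) - F_target

    hi = R
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, 0.0, hi, xtol=1e-18)


# -- results writer --------------------------------------------------------

def write_results(results: list[KVMResults], path: str | Path) -> Path:
    """One CSV row per fitted curve plus a JSON provenance sidecar."""
    import json

    import pandas as pd

    path = Path(path)
    pd.DataFrame([r.to_row() for r in results]).to_csv(path, index=False)
    if results:
        c = results[0].model.constants
        nu = results[0].params.nu
    else:
        c, nu = CalibrationConstants(), 0.5
    prov = {
        "software": "kvmfit", "version": _version,
        "constants": {"alpha1": c.alpha1, "alpha2": c.alpha2,
                      "alpha3": c.alpha3, "alpha4": c.alpha4},
        "nu": nu, "n_curves": len(results),
    }
    path.with_suffix(".provenance.json").write_text(json.dumps(prov, indent=1))
    return path
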