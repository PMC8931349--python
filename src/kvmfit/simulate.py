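"""Synthetic approach curves and an independent hereditary-integral oracle.

The generator forward-evaluates the explicit KVM force-indentation relation
on a constant-velocity approach, adds a linear baseline and i.i.d. Gaussian
force noise, and encodes the result in the same piezo-height/force layout an
instrument would produce — so the whole pipeline (reader, separation
correction, contact point, fit) can be exercised round-trip against known
ground truth.

The hereditary-integral oracle evaluates the viscoelastic contact force from
first principles instead: the Lee-Radok-type convolution of the KVM
relaxation function ``phi(t) = E0 + E1 exp(-t/lam) + eta*dirac(t)`` with the
rate of ``delta^(3/2)``,

    F(t) = 4/(3(1-nu^2)) sqrt(R) [ int_0^t (E0 + E1 e^{-(t-tau)/lam})
                                   d/dtau delta^{3/2}(tau) dtau
                                   + eta (3/2) sqrt(delta(t)) delta'(t) ]

with the Dirac term integrated in closed form.  It shares no code with the
explicit relation, so agreement between the two is a meaningful check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import CurveMeta, ForceCurve, write_curve
from .models import CalibrationConstants, ProbeGeometry, ViscoelasticParams, kvm_force

__all__ = [
    "SyntheticCurveSpec",
    "generate_kvm_curve",
    "hereditary_integral_force",
    "generate_dataset",
]

MIN_APPROACH_SAMPLES = 200


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Recipe for one synthetic approach curve.

    Defaults emulate the study conditions for spherical-probe indentation of
    soft matter: a 2.5 um bead approaching at 5 um/s to a depth of 0.88 um,
    ~0.05 N/m cantilever, sampled at 10 kHz (>= 200 approach samples).
    """

    params: ViscoelasticParams = field(
        default_factory=lambda: ViscoelasticParams(E0=1000.0, E1=800.0, lam=0.1, eta=1.0)
    )
    geom: ProbeGeometry = field(default_factory=lambda: ProbeGeometry(R=2.5e-6))
    v: float = 5e-6                 # approach speed [m/s]
    delta_max: float = 0.88e-6      # final indentation depth [m]
    sampling_rate: float = 10000.0  # [Hz]
    spring_constant: float = 0.05   # [N/m]
    baseline_m: float = 0.0         # baseline slope on the separation axis [N/m]
    baseline_d: float = 0.0         # baseline force offset [N]
    cp_offset: float = 0.8e-6       # contact position on the separation axis [m]
    noise_sigma: float = 0.0        # additive Gaussian force noise [N]
    include_retract: bool = False   # mirrored, force-free retract ramp
    constants: CalibrationConstants = field(default_factory=CalibrationConstants)
    group: str | None = None
    cell_id: str | None = None
    curve_id: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v <= 0 or self.delta_max <= 0 or self.sampling_rate <= 0:
            raise ValueError("v, delta_max and sampling_rate must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.cp_offset <= 0:
            raise ValueError("cp_offset must be positive (need a baseline)")
        n = self.n_approach
        if n < MIN_APPROACH_SAMPLES:
            raise ValueError(
                f"spec yields {n} approach samples; need >= {MIN_APPROACH_SAMPLES} "
                "(raise sampling_rate or lengthen the ramp)"
            )

    @property
    def n_approach(self) -> int:
        return int(round((self.cp_offset + self.delta_max) / self.v * self.sampling_rate)) + 1


def _model_force(spec: SyntheticCurveSpec, delta: np.ndarray) -> np.ndarray:
    """Baseline + KVM force at (possibly negative) indentation delta."""
    g = spec.geom
    if g.Rcell is not None:
        # sphere-on-sphere: effective radius in the force law, confinement
        # factor applied to the indentation (same convention the fitter uses)
        d_eff = g.K * np.maximum(delta, 0.0)
        F = kvm_force(spec.params, spec.constants, g.Reff, spec.v, d_eff, clip=True)
    else:
        F = kvm_force(spec.params, spec.constants, g.R, spec.v, delta, clip=True)
    return F + spec.baseline_m * delta + spec.baseline_d


def generate_kvm_curve(spec: SyntheticCurveSpec) -> ForceCurve:
    """Generate one synthetic approach curve (identical spec+seed => identical arrays).

    The tip advances along the separation axis at constant speed; contact
    occurs at ``cp_offset``.  The piezo trace is reconstructed from the
    noiseless force so that the separation correction ``s = -z - F/k``
    round-trips exactly; noise is then added to the recorded force channel.
    Ground truth is embedded in ``meta.extras['truth']`` for test harnesses.
    """
    n = spec.n_approach
    t = np.arange(n) / spec.sampling_rate
    s = spec.v * t
    delta = s - spec.cp_offset
    F_clean = _model_force(spec, delta)
    z = -s - F_clean / spec.spring_constant
    segment = np.full(n, "approach", dtype=object)

    if spec.include_retract:
        # mirrored ramp carrying baseline force only (for segment-split tests)
        s_r = s[-1] - spec.v * t[1:]
        F_r = spec.baseline_m * (s_r - spec.cp_offset) + spec.baseline_d
        z = np.concatenate([z, -s_r - F_r / spec.spring_constant])
        F_clean = np.concatenate([F_clean, F_r])
        t = np.concatenate([t, t[-1] + (np.arange(1, n)) / spec.sampling_rate])
        segment = np.concatenate([segment, np.full(n - 1, "retract", dtype=object)])

    rng = np.random.default_rng(spec.seed)
    F = F_clean + spec.noise_sigma * rng.standard_normal(len(F_clean))

    truth = {
        "E0": spec.params.E0, "E1": spec.params.E1, "lam": spec.params.lam,
        "eta": spec.params.eta, "nu": spec.params.nu,
        "cp": spec.cp_offset, "delta_max": spec.delta_max, "v": spec.v,
        "baseline_m": spec.baseline_m, "baseline_d": spec.baseline_d,
        "noise_sigma": spec.noise_sigma, "seed": spec.seed,
        "turn_index": n - 1,
    }
    meta = CurveMeta(
        spring_constant=spec.spring_constant,
        velocity=spec.v,
        radius=spec.geom.R,
        cell_radius=spec.geom.Rcell,
        thickness=spec.geom.h,
        approach_only=not spec.include_retract,
        group=spec.group, cell_id=spec.cell_id, curve_id=spec.curve_id,
        extras={"truth": truth},
    )
    return ForceCurve(t, z, F, segment, meta)


def hereditary_integral_force(
    params: ViscoelasticParams,
    R: float,
    delta_history: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Viscoelastic contact force from the hereditary (memory) integral.

    Trapezoidal quadrature of the convolution of the KVM relaxation kernel
    with ``d/dtau delta^(3/2)``, plus the closed-form Dirac (dashpot) term
    ``eta (3/2) sqrt(delta) delta'``.  Approach only: ``delta_history`` must
    be non-decreasing on a uniform time grid of spacing ``dt``.

    Independent of the explicit force-indentation relation by construction
    (no shared code path), so it can serve as an oracle for it.
    """
    delta = np.asarray(delta_history, dtype=float)
    if np.any(np.diff(delta) < -1e-18):
        raise ValueError("delta must be non-decreasing (retraction unsupported)")
    if np.any(delta < 0):
        raise ValueError("delta must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = len(delta)
    pref = 4.0 / (3.0 * (1.0 - params.nu**2)) * math.sqrt(R)

    g = delta**1.5
    gdot = np.gradient(g, dt)
    ddot = np.gradient(delta, dt)
    tau = np.arange(n) * dt

    F = np.empty(n)
    for i in range(n):
        if params.E1 > 0:
            kern = params.E0 + params.E1 * np.exp(-(tau[i] - tau[: i + 1]) / params.lam)
        else:
            kern = np.full(i + 1, params.E0)
        F[i] = np.trapezoid(kern * gdot[: i + 1], dx=dt) if i > 0 else 0.0
    F += params.eta * 1.5 * np.sqrt(delta) * ddot
    return pref * F


def generate_dataset(
    outdir: str | Path,
    group_specs: dict[str, SyntheticCurveSpec],
    *,
    n_cells: int = 4,
    curves_per_cell: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a directory tree of curves grouped by condition, plus a manifest.

    Emulates an experiment layout of several conditions, a handful of cells
    (or gel areas) per condition and triplicate curves per cell.  Per-curve
    seeds are drawn from one :class:`numpy.random.SeedSequence`, so the whole
    tree is reproducible from ``seed``.  Returns the manifest (also written
    to ``manifest.csv``) with one ground-truth row per file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    rows = []
    for gi, (group, base) in enumerate(sorted(group_specs.items())):
        gdir = outdir / group
        gdir.mkdir(exist_ok=True)
        for ci in range(n_cells):
            for ri in range(curves_per_cell):
                child = np.random.SeedSequence(
                    entropy=ss.entropy, spawn_key=(gi, ci, ri)
                )
                curve_seed = int(child.generate_state(1)[0] % (2**31))
                spec = replace(
                    base, group=group, cell_id=f"{group}_cell{ci:02d}",
                    curve_id=f"{group}_cell{ci:02d}_curve{ri}", seed=curve_seed,
                )
                curve = generate_kvm_curve(spec)
                path = gdir / f"{spec.curve_id}.tsv"
                write_curve(curve, path)
                rows.append({
                    "file": str(path.relative_to(outdir)),
                    "group": group, "cell_id": spec.cell_id,
                    "curve_id": spec.curve_id, **curve.meta.extras["truth"],
                })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
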