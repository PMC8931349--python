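"""Force-curve container, plain-text I/O and approach-segment preprocessing.

A curve file is a delimited text table (TSV or CSV) with unit-suffixed header
columns ``time_s``, ``height_m``, ``force_N`` and an optional ``segment``
column (``approach``/``retract``), accompanied by a JSON sidecar
``<stem>.json`` carrying acquisition metadata: spring constant, nominal
approach velocity, probe geometry and optional group/cell identifiers.
Files without the unit-suffixed headers are rejected rather than guessed at.

Sign conventions: the piezo height ``z`` decreases as the probe approaches;
the tip-sample separation axis ``s = -z - F/k`` increases into the sample,
and indentation ``delta = s - cp`` is positive past the contact point ``cp``.
Force is positive in compression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CurveMeta",
    "ForceCurve",
    "read_curve",
    "write_curve",
    "tip_sample_separation",
    "split_segments",
]

REQUIRED_COLUMNS = ("time_s", "height_m", "force_N")


class CurveFormatError(ValueError):
    """Raised for curve files whose layout or metadata is unusable."""


@dataclass
class CurveMeta:
    """Acquisition metadata attached to a force curve (strict SI)."""

    spring_constant: float | None = None   # k [N/m]
    velocity: float | None = None          # nominal approach speed [m/s]
    radius: float | None = None            # bead radius [m]
    cell_radius: float | None = None       # rounded-cell radius [m]
    thickness: float | None = None         # sample thickness [m]
    setpoint: float | None = None          # force setpoint [N]
    approach_only: bool = False
    group: str | None = None
    cell_id: str | None = None
    curve_id: str | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: v for k, v in d.items() if v not in (None, {}, False)}

    @classmethod
    def from_dict(cls, d: dict) -> "CurveMeta":
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in d.items() if k in known}
        extras = dict(d.get("extras", {}))
        extras.update({k: v for k, v in d.items() if k not in known and k != "extras"})
        return cls(extras=extras, **kwargs)


@dataclass
class ForceCurve:
    """Time series of piezo height and force; the unit of analysis."""

    t: np.ndarray
    z: np.ndarray
    F: np.ndarray
    segment: np.ndarray | None = None   # per-sample 'approach' / 'retract'
    meta: CurveMeta = field(default_factory=CurveMeta)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        n = len(self.t)
        if not (len(self.z) == len(self.F) == n):
            raise CurveFormatError("t, z, F must have equal length")
        if 0 < n < 16:  # n == 0 allowed: an empty retract part
            raise CurveFormatError(f"curve too short ({n} samples, need >= 16)")
        if np.any(np.diff(self.t) <= 0):
            raise CurveFormatError("time samples must be strictly increasing")
        if self.segment is not None:
            self.segment = np.asarray(self.segment)
            if len(self.segment) != n:
                raise CurveFormatError("segment labels must match sample count")

    def __len__(self) -> int:
        return len(self.t)

    def slice(self, idx: slice) -> "ForceCurve":
        seg = self.segment[idx] if self.segment is not None else None
        return ForceCurve(self.t[idx], self.z[idx], self.F[idx], seg, self.meta)


def tip_sample_separation(curve: ForceCurve) -> np.ndarray:
    """Deflection-corrected tip position on the separation axis [m].

    ``s = -z - F/k``: the piezo height corrected for the cantilever
    deflection ``F/k``, signed so that ``s`` increases into the sample.
    Requires the spring constant in the curve metadata.
    """
    k = curve.meta.spring_constant
    if k is None or k <= 0:
        raise CurveFormatError("spring constant k missing from curve metadata")
    return -curve.z - curve.F / k


def split_segments(curve: ForceCurve) -> tuple[ForceCurve, ForceCurve]:
    """Split a full indentation cycle into (approach, retract) at the z extremum.

    Uses the explicit ``segment`` labels when present; otherwise splits at the
    global minimum of the piezo height (deepest point).  Curves flagged
    ``approach_only`` return an empty retract part.
    """
    n = len(curve)
    if curve.segment is not None:
        app = curve.segment == "approach"
        i = int(np.max(np.nonzero(app)[0])) + 1 if app.any() else n
    elif curve.meta.approach_only:
        i = n
    else:
        i = int(np.argmin(curve.z)) + 1
    return curve.slice(slice(0, i)), curve.slice(slice(i, n))


def write_curve(curve: ForceCurve, path: str | Path) -> Path:
    """Write a curve as TSV plus a JSON metadata sidecar; returns the TSV path."""
    path = Path(path)
    cols = {"time_s": curve.t, "height_m": curve.z, "force_N": curve.F}
    if curve.segment is not None:
        cols["segment"] = curve.segment
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(curve.meta.to_dict(), indent=1, sort_keys=True))
    return path


def read_curve(path: str | Path) -> ForceCurve:
    """Read a TSV/CSV curve file and its JSON sidecar.

    Rejects files that lack the unit-suffixed columns ``time_s``,
    ``height_m``, ``force_N`` — no unit guessing.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # noqa: BLE001 - any parse failure is a format error
        raise CurveFormatError(f"{path.name}: unreadable curve file ({exc})") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CurveFormatError(
            f"{path.name}: missing unit-suffixed columns {missing}; "
            "expected time_s, height_m, force_N"
        )
    for c in REQUIRED_COLUMNS:
        if not np.issubdtype(df[c].dtype, np.number) or df[c].isna().any():
            raise CurveFormatError(f"{path.name}: column {c} is not clean numeric data")
    meta = CurveMeta()
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = CurveMeta.from_dict(json.loads(sidecar.read_text()))
    if meta.curve_id is None:
        meta.curve_id = path.stem
    seg = df["segment"].to_numpy() if "segment" in df.columns else None
    return ForceCurve(
        df["time_s"].to_numpy(), df["height_m"].to_numpy(),
        df["force_N"].to_numpy(), seg, meta,
    )
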