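"""Stage–discharge rating curves.

A rating curve is a tabulated monotone mapping from discharge (m³/s) to
water-surface stage (m).  Because natural rating curves are close to power
laws, interpolation is done with stage linear in log-discharge by default
("loglog"); a plain linear mode exists for already-linearised tables.  Stage
columns may be negative (curves are routinely re-datumed to a reference
discharge for comparison), so stage itself is never log-transformed.

Extrapolation policy: above the tabulated range the terminal segment is
extended (with a warning — habitat-forming peaks can exceed the rated range);
below the minimum tabulated discharge the stage clamps to the first point
(with a warning).  Inversion is exact on the tabulated range and refuses
stages below the bottom of the table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RatingCurve",
    "RatingCurveError",
    "ExtrapolationWarning",
    "stage_at",
    "discharge_at",
    "normalize",
    "scale_stage_response",
    "read_rating_csv",
    "write_rating_csv",
]


class RatingCurveError(ValueError):
    """Invalid rating-curve data or query."""


class ExtrapolationWarning(UserWarning):
    """A stage/discharge query fell outside the tabulated range."""


@dataclass(frozen=True)
class RatingCurve:
    """Tabulated stage–discharge relationship.

    ``discharge`` must be strictly increasing and positive; ``stage`` strictly
    increasing (a flat segment would make the curve non-invertible and is
    rejected at construction).  ``reference_discharge`` records the datum used
    by :meth:`normalize`, and is the default pivot for sensitivity scaling.
    """

    discharge: np.ndarray
    stage: np.ndarray
    datum_note: str = ""
    source: str = "synthetic"  # gage-rating | hydraulic-model | synthetic
    interpolation: str = "loglog"  # loglog | linear
    reference_discharge: float | None = None

    def __post_init__(self):
        q = np.asarray(self.discharge, dtype=float)
        s = np.asarray(self.stage, dtype=float)
        if q.ndim != 1 or s.shape != q.shape or q.size < 2:
            raise RatingCurveError("need ≥ 2 (discharge, stage) pairs of equal length")
        if (q <= 0).any():
            raise RatingCurveError("discharges must be positive")
        if (np.diff(q) <= 0).any():
            raise RatingCurveError("discharge column must be strictly increasing")
        if (np.diff(s) <= 0).any():
            raise RatingCurveError(
                "stage column must be strictly increasing (flat segments are not invertible)"
            )
        if self.interpolation not in ("loglog", "linear"):
            raise RatingCurveError(f"unknown interpolation {self.interpolation!r}")
        object.__setattr__(self, "discharge", q)
        object.__setattr__(self, "stage", s)

    # -- coordinates ---------------------------------------------------------

    def _x(self, q):
        return np.log(q) if self.interpolation == "loglog" else np.asarray(q, float)

    def _q_from_x(self, x):
        return np.exp(x) if self.interpolation == "loglog" else x

    # -- queries -------------------------------------------------------------

    def stage_at(self, discharge) -> float | np.ndarray:
        """Stage (m) at the given discharge(s), interpolating the table."""
        scalar = np.isscalar(discharge)
        q = np.atleast_1d(np.asarray(discharge, dtype=float))
        if (q <= 0).any():
            raise RatingCurveError("discharge must be positive")
        x = self._x(q)
        xs = self._x(self.discharge)
        s = np.interp(x, xs, self.stage)
        above = x > xs[-1]
        if above.any():
            slope = (self.stage[-1] - self.stage[-2]) / (xs[-1] - xs[-2])
            s[above] = self.stage[-1] + slope * (x[above] - xs[-1])
            warnings.warn(
                "discharge above tabulated range; extrapolating terminal segment",
                ExtrapolationWarning,
                stacklevel=2,
            )
        below = x < xs[0]
        if below.any():
            s[below] = self.stage[0]
            warnings.warn(
                "discharge below tabulated range; stage clamped to first point",
                ExtrapolationWarning,
                stacklevel=2,
            )
        return float(s[0]) if scalar else s

    def discharge_at(self, stage) -> float | np.ndarray:
        """Discharge (m³/s) whose stage equals ``stage`` — the inverse query."""
        scalar = np.isscalar(stage)
        s = np.atleast_1d(np.asarray(stage, dtype=float))
        if (s < self.stage[0]).any():
            raise RatingCurveError(
                f"stage below the curve minimum ({self.stage[0]:.3f} m); not invertible there"
            )
        xs = self._x(self.discharge)
        x = np.interp(s, self.stage, xs)
        above = s > self.stage[-1]
        if above.any():
            slope = (xs[-1] - xs[-2]) / (self.stage[-1] - self.stage[-2])
            x[above] = xs[-1] + slope * (s[above] - self.stage[-1])
            warnings.warn(
                "stage above tabulated range; extrapolating terminal segment",
                ExtrapolationWarning,
                stacklevel=2,
            )
        q = self._q_from_x(x)
        return float(q[0]) if scalar else q

    # -- transforms ----------------------------------------------------------

    def normalize(self, reference_discharge: float, reference_stage: float = 0.0) -> "RatingCurve":
        """Shift all stages so ``stage_at(reference_discharge) == reference_stage``.

        Shape is unchanged; only the datum moves.  The reference must lie
        within the tabulated discharge range.
        """
        if not (self.discharge[0] <= reference_discharge <= self.discharge[-1]):
            raise RatingCurveError("normalization reference outside tabulated range")
        shift = reference_stage - self.stage_at(reference_discharge)
        return replace(
            self,
            stage=self.stage + shift,
            datum_note=f"normalized: stage {reference_stage} m at {reference_discharge} m³/s",
            reference_discharge=float(reference_discharge),
        )

    def scale_stage_response(
        self, factor: float, pivot_discharge: float | None = None
    ) -> "RatingCurve":
        """Multiply stage rise per unit discharge by ``factor`` about a pivot.

        ``s'(Q) = s(pivot) + factor · (s(Q) − s(pivot))``.  Used for the
        sensitivity analysis that varies stage-per-unit-discharge between 70%
        and 130% of the base curve.  Pivot defaults to the normalization
        reference, else the lowest tabulated discharge.
        """
        if factor <= 0:
            raise RatingCurveError("scale factor must be positive")
        pivot = pivot_discharge
        if pivot is None:
            pivot = self.reference_discharge
        if pivot is None:
            pivot = float(self.discharge[0])
        if not (self.discharge[0] <= pivot <= self.discharge[-1]):
            raise RatingCurveError("pivot discharge outside tabulated range")
        sp = self.stage_at(pivot)
        return replace(self, stage=sp + factor * (self.stage - sp))


# -- module-level thin wrappers (the functional surface) ----------------------


def stage_at(curve: RatingCurve, discharge):
    return curve.stage_at(discharge)


def discharge_at(curve: RatingCurve, stage):
    return curve.discharge_at(stage)


def normalize(curve: RatingCurve, reference_discharge: float, reference_stage: float = 0.0):
    return curve.normalize(reference_discharge, reference_stage)


def scale_stage_response(curve: RatingCurve, factor: float, pivot_discharge: float | None = None):
    return curve.scale_stage_response(factor, pivot_discharge)


# -- I/O ----------------------------------------------------------------------


def write_rating_csv(curve: RatingCurve, path) -> None:
    lines = [f"# source: {curve.source}"]
    if curve.datum_note:
        lines.append(f"# datum: {curve.datum_note}")
    lines.append("discharge_cms,stage_m")
    for q, s in zip(curve.discharge, curve.stage):
        lines.append(f"{float(q)!r},{float(s)!r}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_rating_csv(path, **kwargs) -> RatingCurve:
    """Read a two-column (discharge_cms, stage_m) CSV with optional # metadata."""
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    source = kwargs.pop("source", "gage-rating")
    datum = ""
    rows = []
    header_seen = False
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            meta = line.lstrip("#").strip()
            if meta.lower().startswith("source:"):
                source = meta.split(":", 1)[1].strip()
            elif meta.lower().startswith("datum:"):
                datum = meta.split(":", 1)[1].strip()
            continue
        if not header_seen and not line[0].isdigit():
            header_seen = True
            continue
        q_str, s_str = line.split(",")[:2]
        rows.append((float(q_str), float(s_str)))
    if not rows:
        raise RatingCurveError("empty rating table")
    q, s = map(np.array, zip(*rows))
    return RatingCurve(q, s, datum_note=datum, source=source, **kwargs)
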