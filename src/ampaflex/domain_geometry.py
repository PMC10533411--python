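"""Centers of mass, principal axes, and NTD dimer tilt/splay angles.

The splay angle of an NTD dimer is the angle between the dimer's local
two-fold axis (its second principal axis) and the global two-fold axis of a
reference receptor (its first principal axis), computed as the arccosine of
the dot product of the unit axes.  Angles are reported in degrees with
0 = upright-parallel, and the full [0°, 180°] range is retained so that
dimers splayed past horizontal remain distinguishable.

Eigenvectors are sign-ambiguous, so axes are canonically oriented before the
angle is taken: the dimer axis is oriented "outward/up" (positive dot product
with the vector from the whole-receptor COM to the dimer COM) and the
reference axis is oriented toward the NTD end of the receptor.  When the
raw sign-canonicalized eigenvector pointed down towards the LBD, the raw
arccos value is replaced by its 180° complement and the result is flagged
``corrected`` — equivalently, the reported angle is always measured from the
outward-oriented dimer axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import (
    DomainSelection,
    StructureModel,
    select_calpha,
)

_ORTHO_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Point set too degenerate for the requested geometric quantity."""


@dataclass
class PrincipalAxes:
    """COM-centred orthonormal axes ordered by descending positional variance."""

    origin: np.ndarray  # (3,) COM in Å
    axes: np.ndarray  # (3, 3), rows are unit vectors
    variances: np.ndarray  # (3,) in Å², descending

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.axes = np.asarray(self.axes, float)
        self.variances = np.asarray(self.variances, float)
        gram = self.axes @ self.axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")
        if np.any(np.diff(self.variances) > 1e-9):
            raise ValueError("variances must be sorted descending")

    @property
    def is_collinear(self) -> bool:
        """True when the point set had (numerically) no second direction."""
        scale = max(self.variances[0], 1.0)
        return bool(self.variances[1] < 1e-9 * scale)


@dataclass
class SplayAngles:
    """Tilt/splay angle pair (a, b) of a model's two NTD dimers, degrees."""

    model_id: str
    angle_a: float
    angle_b: float
    corrected_a: bool
    corrected_b: bool

    def __post_init__(self) -> None:
        for ang in (self.angle_a, self.angle_b):
            if not (0.0 <= ang <= 180.0):
                raise ValueError(f"splay angle {ang} outside [0, 180] degrees")


def center_of_mass(coords: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted mean position; equal weights by default (Cα-only analyses)."""
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise ValueError("coords must be a non-empty (n, 3) array")
    if weights is None:
        return coords.mean(axis=0)
    weights = np.asarray(weights, float)
    if weights.shape != (coords.shape[0],):
        raise ValueError("weights must match number of coordinates")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must sum to a positive value")
    return (coords * weights[:, None]).sum(axis=0) / total


def _canonical_sign(vec: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector sign: first component with |x| > tol positive."""
    for x in vec:
        if abs(x) > 1e-12:
            return vec if x > 0 else -vec
    return vec


def principal_axes(coords: np.ndarray) -> PrincipalAxes:
    """Eigen-decompose the 3×3 positional covariance about the COM.

    Equal-weight positional covariance (not a mass-weighted inertia tensor):
    the pipeline operates on Cα ensembles where atom masses are uniform.
    Collinear point sets are allowed (flagged via ``is_collinear``); a set of
    identical points is rejected.
    """
    coords = np.asarray(coords, float)
    com = center_of_mass(coords)
    centred = coords - com
    cov = centred.T @ centred / coords.shape[0]
    if float(np.trace(cov)) < 1e-18:
        raise DegenerateGeometryError("all points coincide; axes undefined")
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    axes = np.array([_canonical_sign(evecs[:, i]) for i in order])
    return PrincipalAxes(origin=com, axes=axes, variances=evals)


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise DegenerateGeometryError(f"{what} has zero length")
    return v / n


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two vectors, arccos argument clamped to [-1, 1]."""
    uu = _unit(np.asarray(u, float), "first vector")
    vv = _unit(np.asarray(v, float), "second vector")
    return float(np.degrees(np.arccos(np.clip(np.dot(uu, vv), -1.0, 1.0))))


def dimer_tilt_angle(
    dimer_axes: PrincipalAxes,
    reference_axes: PrincipalAxes,
    dimer_com: np.ndarray,
    reference_top: np.ndarray,
) -> tuple[float, bool]:
    """Tilt of one NTD dimer against the reference receptor's global axis.

    Returns ``(angle_deg, corrected)``.  ``corrected`` is True when the
    sign-canonicalized dimer eigenvector pointed down towards the LBD, i.e.
    the raw arccos value was replaced by its 180° complement.
    """
    r = _unit(np.asarray(reference_axes.axes[0], float), "reference first axis")
    top = np.asarray(reference_top, float)
    if np.dot(r, top - reference_axes.origin) < 0:
        r = -r
    d_raw = _unit(np.asarray(dimer_axes.axes[1], float), "dimer second axis")
    outward = np.asarray(dimer_com, float) - reference_axes.origin
    if float(np.linalg.norm(outward)) < 1e-12:
        raise DegenerateGeometryError("dimer COM coincides with receptor COM")
    corrected = bool(np.dot(d_raw, outward) < 0)
    d = -d_raw if corrected else d_raw
    angle = float(np.degrees(np.arccos(np.clip(np.dot(d, r), -1.0, 1.0))))
    return angle, corrected


def splay_landscape(
    models: list[StructureModel],
    reference: StructureModel,
    dimer_selections: dict[str, DomainSelection],
    reference_selection: DomainSelection,
    reference_top: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-model (a, b) splay-angle table for an ensemble of fitted models.

    ``dimer_selections`` maps the two dimer identities (sorted order defines
    which is "a" and which is "b") to their chain/residue selections; the
    assignment is therefore configuration-driven and deterministic.
    ``reference_top`` defaults to one Å above the reference COM along +z
    (the conventional vertical axis).
    """
    if len(dimer_selections) != 2:
        raise ValueError("exactly two NTD dimer selections are required")
    ref_xyz, _ = select_calpha(reference, reference_selection)
    ref_axes = principal_axes(ref_xyz)
    if reference_top is None:
        reference_top = ref_axes.origin + np.array([0.0, 0.0, 1.0])

    dimer_ids = sorted(dimer_selections)
    rows = []
    for model in models:
        angles: dict[str, float] = {}
        flags: dict[str, bool] = {}
        for dimer_id in dimer_ids:
            sel = dimer_selections[dimer_id]
            try:
                xyz, _ = select_calpha(model, sel)
            except Exception as exc:
                raise type(exc)(
                    f"model {model.model_id!r}, dimer {dimer_id!r}: {exc}"
                ) from exc
            axes = principal_axes(xyz)
            angles[dimer_id], flags[dimer_id] = dimer_tilt_angle(
                axes, ref_axes, axes.origin, reference_top
            )
        a_id, b_id = dimer_ids
        rows.append(
            {
                "model_id": model.model_id,
                "angle_a_deg": angles[a_id],
                "angle_b_deg": angles[b_id],
                "corrected_a": flags[a_id],
                "corrected_b": flags[b_id],
            }
        )
    return pd.DataFrame(rows)
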