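"""LBD rotation angles about vertical anchor axes.

Desensitized LBD subunits rotate about nearly vertical axes through the
stable anchor residues at the start of the S1–M1 linker (K501 in GluA1,
K505 in GluA2).  For each chain, the anchor centre of mass pooled across all
structures fixes the x, y position of a rotation axis parallel to z; the
helix-G centre of mass of each individual structure is the proxy point whose
excursion around that axis measures the rotation.  The vertex of the angle
is the "reference point" (anchor x, y; pooled helix-G z) and its two rays go
to the model's helix-G COM and to the helix-G COM of the matching chain of a
reference structure.

All structures must be pre-superposed into a common frame whose z axis is
the global symmetry axis.  Pooled ("combined") COMs weight each structure
equally, not each atom, so models with different helix-G atom counts
contribute equally; the reference structure participates in the pooling.

Two angle modes are provided: ``vertex3d`` (the plain three-point angle) and
``projected_xy`` (the same after zeroing z components, i.e. a pure rotation
about the vertical axis).  When the three points share one z value the two
agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain_geometry import DegenerateGeometryError, center_of_mass
from .structure_io import (
    DomainSelection,
    PairingError,
    StructureModel,
    select_atoms,
)

MODES = ("vertex3d", "projected_xy")


@dataclass
class RotationFrame:
    """Per-chain geometry against which one structure's rotation is measured."""

    chain_id: str
    anchor_com: np.ndarray  # pooled anchor COM (combined K-residue COM)
    reference_point: np.ndarray  # x, y of anchor_com; z of pooled helix-G COM
    reference_proxy: np.ndarray  # helix-G COM of the reference structure's chain

    def __post_init__(self) -> None:
        self.anchor_com = np.asarray(self.anchor_com, float)
        self.reference_point = np.asarray(self.reference_point, float)
        self.reference_proxy = np.asarray(self.reference_proxy, float)
        if not np.array_equal(self.reference_point[:2], self.anchor_com[:2]):
            raise ValueError("reference_point must share x, y with anchor_com")


@dataclass
class RotationAngleResult:
    model_id: str
    chain_id: str
    angle: float  # degrees in [0, 180]
    mode: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.angle) or not (0.0 <= self.angle <= 180.0):
            raise ValueError(f"angle {self.angle} outside [0, 180] degrees")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


def _per_chain_com(
    model: StructureModel, sel: DomainSelection, chains: list[str]
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    coords, labels = select_atoms(model, sel)
    chain_arr = np.array([lab[0] for lab in labels], dtype=object)
    for chain in chains:
        mask = chain_arr == chain
        if not mask.any():
            raise PairingError(
                f"selection {sel.name!r} matches no atoms on chain {chain!r} "
                f"in model {model.model_id!r}"
            )
        out[chain] = center_of_mass(coords[mask])
    return out


def build_rotation_frames(
    models: list[StructureModel],
    reference: StructureModel,
    anchors: DomainSelection,
    helix_g: DomainSelection,
) -> dict[str, RotationFrame]:
    """Per-chain rotation frames pooled across all structures.

    Every chain named by the selections must resolve in every model and in
    the reference; pooled COMs average per-structure COMs with equal weight.
    """
    chains = sorted(set(anchors.chains()) | set(helix_g.chains()))
    structures = [reference, *models]
    anchor_coms = {c: [] for c in chains}
    helixg_coms = {c: [] for c in chains}
    for structure in structures:
        a = _per_chain_com(structure, anchors, chains)
        h = _per_chain_com(structure, helix_g, chains)
        for c in chains:
            anchor_coms[c].append(a[c])
            helixg_coms[c].append(h[c])
    ref_proxy = _per_chain_com(reference, helix_g, chains)

    frames: dict[str, RotationFrame] = {}
    for c in chains:
        anchor = np.mean(anchor_coms[c], axis=0)
        pooled_hg = np.mean(helixg_coms[c], axis=0)
        ref_point = np.array([anchor[0], anchor[1], pooled_hg[2]])
        frames[c] = RotationFrame(
            chain_id=c,
            anchor_com=anchor,
            reference_point=ref_point,
            reference_proxy=ref_proxy[c],
        )
    return frames


def rotation_angle(
    frame: RotationFrame,
    helix_g_com_of_model: np.ndarray,
    mode: str = "vertex3d",
    model_id: str = "",
) -> RotationAngleResult:
    """Angle at the reference point between a model's helix-G COM and the
    reference structure's helix-G COM."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    p = np.asarray(helix_g_com_of_model, float)
    v1 = p - frame.reference_point
    v2 = frame.reference_proxy - frame.reference_point
    if mode == "projected_xy":
        v1 = np.array([v1[0], v1[1], 0.0])
        v2 = np.array([v2[0], v2[1], 0.0])
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-6 or n2 < 1e-6:
        raise DegenerateGeometryError(
            f"chain {frame.chain_id!r}: degenerate geometry "
            f"(ray lengths {n1:.2e}, {n2:.2e} Å)"
        )
    u, w = v1 / n1, v2 / n2
    # 2·atan2(|u−w|, |u+w|) is the arccos of the clamped dot product, but
    # numerically stable near 0° and 180°
    angle = 2.0 * np.arctan2(np.linalg.norm(u - w), np.linalg.norm(u + w))
    return RotationAngleResult(
        model_id=model_id,
        chain_id=frame.chain_id,
        angle=float(np.degrees(angle)),
        mode=mode,
    )


def rotation_table(
    models: list[StructureModel],
    reference: StructureModel,
    anchors: DomainSelection,
    helix_g: DomainSelection,
    mode: str = "vertex3d",
) -> pd.DataFrame:
    """Rotation angles for every (model, chain), in deterministic order.

    ``mode`` may be ``vertex3d``, ``projected_xy`` or ``both`` (one column
    per mode).  Rows are ordered by model input order, then chain id.
    """
    modes = list(MODES) if mode == "both" else [mode]
    for m in modes:
        if m not in MODES:
            raise ValueError(f"unknown mode {m!r}")
    frames = build_rotation_frames(models, reference, anchors, helix_g)
    chains = sorted(frames)
    rows = []
    for model in models:
        hg = _per_chain_com(model, helix_g, chains)
        for c in chains:
            row: dict[str, object] = {"model_id": model.model_id, "chain_id": c}
            for m in modes:
                res = rotation_angle(frames[c], hg[c], mode=m, model_id=model.model_id)
                key = "angle_deg" if len(modes) == 1 else f"angle_{m}_deg"
                row[key] = res.angle
            if len(modes) == 1:
                row["mode"] = modes[0]
            rows.append(row)
    return pd.DataFrame(rows)
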