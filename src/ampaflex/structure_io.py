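"""Reading, selecting, superposing and writing atomic coordinate models.

Coordinates are in Å throughout, in a right-handed frame where z is the
vertical/global-symmetry axis by convention.  Residue numbering follows the
input file verbatim (1-based author numbering); no renumbering is performed.
Alternate locations are resolved deterministically by keeping the first
altloc in identifier order, with a logged warning per affected residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import yaml

logger = logging.getLogger(__name__)

SELECTION_ROLES = frozenset(
    {"ntd_dimer", "lbd_subunit", "helix_g", "anchor_residue", "reference_body"}
)


class FormatError(ValueError):
    """Input file could not be parsed in the named format."""


class PairingError(ValueError):
    """Atom labels could not be matched one-to-one between structures."""


class DegenerateSelectionError(ValueError):
    """A selection resolved to too few atoms for downstream geometry."""


AtomLabel = tuple[str, int, str]  # (chain_id, residue_number, atom_name)


@dataclass
class StructureModel:
    """Labelled atomic coordinates of one conformer.

    Parallel arrays over atoms; ``(chain_id, residue_number, atom_name)``
    must be unique within a model and all positions finite.
    """

    model_id: str
    chain_ids: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.chain_ids)
        if n == 0:
            raise FormatError(f"model {self.model_id!r} contains no atoms")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"model {self.model_id!r} has non-finite coordinates")
        labels = self.labels()
        if len(set(labels)) != n:
            raise ValueError(
                f"model {self.model_id!r} has duplicate (chain, residue, atom) labels"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.chain_ids)

    def labels(self) -> list[AtomLabel]:
        return [
            (c, int(r), a)
            for c, r, a in zip(self.chain_ids, self.residue_numbers, self.atom_names)
        ]

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c, None)
        return list(seen)

    def copy(self, model_id: str | None = None) -> "StructureModel":
        return StructureModel(
            model_id=model_id or self.model_id,
            chain_ids=self.chain_ids.copy(),
            residue_numbers=self.residue_numbers.copy(),
            residue_names=self.residue_names.copy(),
            atom_names=self.atom_names.copy(),
            coords=self.coords.copy(),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with coordinates mapped through x -> R x + t."""
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation, float).T + np.asarray(
            translation, float
        )
        return out


@dataclass(frozen=True)
class SelectionMember:
    chain_id: str
    res_start: int
    res_end: int
    atom_name: str | None = None

    def __post_init__(self) -> None:
        if self.res_end < self.res_start:
            raise ValueError(
                f"empty residue range {self.res_start}..{self.res_end} "
                f"on chain {self.chain_id!r}"
            )


@dataclass(frozen=True)
class DomainSelection:
    """Named set of chain/residue ranges with a structural role annotation."""

    name: str
    members: tuple[SelectionMember, ...]
    role: str = "reference_body"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"selection {self.name!r} has no members")
        if self.role not in SELECTION_ROLES:
            raise ValueError(f"unknown selection role {self.role!r}")

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(m.chain_id, None)
        return list(seen)


@dataclass
class AtomMatchedEnsemble:
    """Atom-matched conformer stack: one position per label per frame."""

    atom_labels: list[AtomLabel]
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    residue_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.frames.shape[1] != len(self.atom_labels):
            raise ValueError("frame width does not match atom_labels")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# reading / writing


def _resolve_format(path: Path, fmt: str | None) -> gemmi.CoorFormat:
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "mmcif" if suffix in {".cif", ".mmcif"} else "pdb"
    try:
        return {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}[fmt]
    except KeyError:
        raise FormatError(f"unknown coordinate format {fmt!r}") from None


def read_model(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read one coordinate model from a PDB or mmCIF file.

    Only the first MODEL block is used.  Alternate locations are resolved by
    keeping the first altloc in identifier order (a warning is logged per
    affected residue); insertion codes are folded into the author residue
    number ordering as gemmi reports them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_structure(str(path), format=_resolve_format(path, fmt))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path} as {fmt or 'auto'}: {exc}") from exc
    if len(structure) == 0:
        raise FormatError(f"{path}: file contains no coordinate models")
    model = structure[0]

    chain_ids: list[str] = []
    res_numbers: list[int] = []
    res_names: list[str] = []
    atom_names: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for chain in model:
        for residue in chain:
            picked: dict[str, gemmi.Atom] = {}
            has_alt = False

            def _alt(a: gemmi.Atom) -> str:
                return "" if a.altloc in ("", "\x00") else a.altloc

            for atom in residue:
                if _alt(atom):
                    has_alt = True
                prev = picked.get(atom.name)
                if prev is None or _alt(atom) < _alt(prev):
                    picked[atom.name] = atom
            if has_alt:
                logger.warning(
                    "altloc resolved (first by identifier) in %s %s%d",
                    chain.name,
                    residue.name,
                    residue.seqid.num,
                )
            for atom in residue:  # preserve file order among picked atoms
                if picked.get(atom.name) is atom:
                    chain_ids.append(chain.name)
                    res_numbers.append(residue.seqid.num)
                    res_names.append(residue.name)
                    atom_names.append(atom.name)
                    coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not chain_ids:
        raise FormatError(f"{path}: model contains no atoms")
    return StructureModel(
        model_id=path.stem,
        chain_ids=np.array(chain_ids, dtype=object),
        residue_numbers=np.array(res_numbers, dtype=int),
        residue_names=np.array(res_names, dtype=object),
        atom_names=np.array(atom_names, dtype=object),
        coords=np.array(coords, dtype=float),
    )


def _model_to_gemmi(
    labels: Sequence[AtomLabel],
    coords: np.ndarray,
    residue_names: Sequence[str] | None,
    name: str,
) -> gemmi.Model:
    gmodel = gemmi.Model(name)
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    for i, (chain_id, resnum, atom_name) in enumerate(labels):
        if chain_id not in chains:
            chains[chain_id] = gmodel.add_chain(gemmi.Chain(chain_id))
        key = (chain_id, resnum)
        if key not in residues:
            res = gemmi.Residue()
            res.name = residue_names[i] if residue_names is not None else "ALA"
            res.seqid = gemmi.SeqId(resnum, " ")
            residues[key] = chains[chain_id].add_residue(res)
        atom = gemmi.Atom()
        atom.name = atom_name
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*coords[i])
        residues[key].add_atom(atom)
    return gmodel


def write_model(model: StructureModel, path: str | Path) -> None:
    """Write a single-conformer model as a PDB file."""
    ens = AtomMatchedEnsemble(
        atom_labels=model.labels(),
        frames=model.coords[None, :, :],
        residue_names=list(model.residue_names),
    )
    write_trajectory(ens, path)


def write_trajectory(ensemble: AtomMatchedEnsemble, path: str | Path) -> None:
    """Write an atom-matched ensemble as a multi-model PDB file.

    One MODEL/ENDMDL block per frame, frame order preserved.
    """
    structure = gemmi.Structure()
    structure.name = Path(path).stem
    for i in range(ensemble.n_frames):
        structure.add_model(
            _model_to_gemmi(
                ensemble.atom_labels,
                ensemble.frames[i],
                ensemble.residue_names,
                str(i + 1),
            )
        )
    try:
        structure.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"could not write trajectory to {path}: {exc}") from exc


def read_trajectory(path: str | Path) -> AtomMatchedEnsemble:
    """Read a multi-model PDB file back into an atom-matched ensemble."""
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise FormatError(f"{path}: no models")
    frames = []
    labels: list[AtomLabel] | None = None
    resnames: list[str] | None = None
    for gmodel in structure:
        these_labels: list[AtomLabel] = []
        these_resnames: list[str] = []
        xyz: list[tuple[float, float, float]] = []
        for chain in gmodel:
            for residue in chain:
                for atom in residue:
                    these_labels.append((chain.name, residue.seqid.num, atom.name))
                    these_resnames.append(residue.name)
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
        if labels is None:
            labels, resnames = these_labels, these_resnames
        elif these_labels != labels:
            raise PairingError(f"{path}: frames have mismatched atom labels")
        frames.append(xyz)
    assert labels is not None
    return AtomMatchedEnsemble(
        atom_labels=labels, frames=np.asarray(frames, float), residue_names=resnames
    )


# ---------------------------------------------------------------------------
# selection


def _selection_mask(model: StructureModel, sel: DomainSelection) -> np.ndarray:
    present = set(model.chains())
    missing = [c for c in sel.chains() if c not in present]
    if missing:
        raise PairingError(
            f"selection {sel.name!r}: chains {missing} absent from model "
            f"{model.model_id!r}"
        )
    mask = np.zeros(model.n_atoms, dtype=bool)
    for m in sel.members:
        hit = (
            (model.chain_ids == m.chain_id)
            & (model.residue_numbers >= m.res_start)
            & (model.residue_numbers <= m.res_end)
        )
        if m.atom_name is not None:
            hit &= model.atom_names == m.atom_name
        mask |= hit
    return mask


def select_atoms(
    model: StructureModel, sel: DomainSelection, atom_name: str | None = None
) -> tuple[np.ndarray, list[AtomLabel]]:
    """Resolve a selection on a model, ordered by (chain_id, residue_number).

    Returns coordinates and the matching atom labels.  ``atom_name`` adds an
    extra atom-name filter on top of any per-member filters.
    """
    mask = _selection_mask(model, sel)
    if atom_name is not None:
        mask &= model.atom_names == atom_name
    idx = np.nonzero(mask)[0]
    order = sorted(
        idx,
        key=lambda i: (model.chain_ids[i], int(model.residue_numbers[i]), model.atom_names[i]),
    )
    order = np.asarray(order, dtype=int)
    labels = [
        (model.chain_ids[i], int(model.residue_numbers[i]), model.atom_names[i])
        for i in order
    ]
    return model.coords[order], labels


def select_calpha(
    model: StructureModel, sel: DomainSelection
) -> tuple[np.ndarray, list[AtomLabel]]:
    """Cα coordinates within a selection, ordered by (chain, residue).

    Raises :class:`DegenerateSelectionError` when fewer than three Cα atoms
    match (downstream axis/angle geometry needs non-degenerate point sets).
    """
    coords, labels = select_atoms(model, sel, atom_name="CA")
    if len(labels) < 3:
        raise DegenerateSelectionError(
            f"selection {sel.name!r} matched only {len(labels)} CA atoms "
            f"in model {model.model_id!r} (need >= 3)"
        )
    return coords, labels


# ---------------------------------------------------------------------------
# superposition


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets (no scaling).

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best fits
    ``target``.  The SVD sign correction guarantees a proper rotation
    (det R = +1), never a reflection.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise DegenerateSelectionError("superposition needs >= 3 paired atoms")
    p_mean = P.mean(axis=0)
    q_mean = Q.mean(axis=0)
    H = (P - p_mean).T @ (Q - q_mean)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = q_mean - R @ p_mean
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    fit_selection: DomainSelection,
) -> tuple[StructureModel, float]:
    """Superpose ``mobile`` onto ``reference`` over a Cα fit selection.

    Atoms are paired by (chain, residue, atom) label; the full mobile model
    is transformed and the RMSD over the fit selection is returned.
    """
    mob_xyz, mob_labels = select_calpha(mobile, fit_selection)
    ref_xyz, ref_labels = select_calpha(reference, fit_selection)
    if mob_labels != ref_labels:
        unmatched = sorted(set(mob_labels) ^ set(ref_labels))
        raise PairingError(
            f"fit selection {fit_selection.name!r} pairs differently in "
            f"{mobile.model_id!r} and {reference.model_id!r}; unmatched labels: "
            f"{unmatched[:10]}{'...' if len(unmatched) > 10 else ''}"
        )
    R, t, rmsd = kabsch(mob_xyz, ref_xyz)
    return mobile.transformed(R, t), rmsd


def ensemble_from_models(
    models: Iterable[StructureModel],
    selection: DomainSelection | None = None,
    calpha_only: bool = True,
) -> AtomMatchedEnsemble:
    """Stack models into an atom-matched ensemble by (chain, residue, atom) label.

    Atom correspondence is taken from the first model (optionally restricted
    to a selection and/or Cα atoms); every other model must resolve the same
    labels exactly.
    """
    models = list(models)
    if not models:
        raise ValueError("no models given")

    def resolve(model: StructureModel) -> tuple[np.ndarray, list[AtomLabel]]:
        if selection is not None:
            if calpha_only:
                return select_calpha(model, selection)
            return select_atoms(model, selection)
        if calpha_only:
            mask = model.atom_names == "CA"
            if int(mask.sum()) < 3:
                raise DegenerateSelectionError(
                    f"model {model.model_id!r} has fewer than 3 CA atoms"
                )
            idx = np.nonzero(mask)[0]
            order = sorted(
                idx, key=lambda i: (model.chain_ids[i], int(model.residue_numbers[i]))
            )
            order = np.asarray(order, int)
            labels = [
                (model.chain_ids[i], int(model.residue_numbers[i]), "CA") for i in order
            ]
            return model.coords[order], labels
        labels = model.labels()
        return model.coords, labels

    first_xyz, labels = resolve(models[0])
    frames = [first_xyz]
    for model in models[1:]:
        xyz, these = resolve(model)
        if these != labels:
            unmatched = sorted(set(these) ^ set(labels))
            raise PairingError(
                f"model {model.model_id!r} does not match the ensemble labels; "
                f"unmatched: {unmatched[:10]}{'...' if len(unmatched) > 10 else ''}"
            )
        frames.append(xyz)
    return AtomMatchedEnsemble(atom_labels=labels, frames=np.asarray(frames, float))


# ---------------------------------------------------------------------------
# selection config files


def load_selections(path: str | Path) -> dict[str, DomainSelection]:
    """Load named selections from a YAML config.

    Schema::

        selections:
          dimer_a:
            role: ntd_dimer
            members:
              - {chain: A, start: 101, end: 124}
              - {chain: B, start: 101, end: 124, atom: CA}

    A single residue may be given as ``resi`` instead of start/end.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "selections" not in data:
        raise FormatError(f"{path}: expected a top-level 'selections' mapping")
    out: dict[str, DomainSelection] = {}
    for name, spec in data["selections"].items():
        members = []
        for m in spec.get("members", []):
            if "resi" in m:
                start = end = int(m["resi"])
            else:
                start, end = int(m["start"]), int(m["end"])
            members.append(
                SelectionMember(
                    chain_id=str(m["chain"]),
                    res_start=start,
                    res_end=end,
                    atom_name=m.get("atom"),
                )
            )
        out[name] = DomainSelection(
            name=name, members=tuple(members), role=spec.get("role", "reference_body")
        )
    return out


def dump_selections(selections: dict[str, DomainSelection], path: str | Path) -> None:
    """Write selections to the YAML schema read by :func:`load_selections`."""
    data = {
        "selections": {
            name: {
                "role": sel.role,
                "members": [
                    {
                        "chain": m.chain_id,
                        "start": m.res_start,
                        "end": m.res_end,
                        **({"atom": m.atom_name} if m.atom_name else {}),
                    }
                    for m in sel.members
                ],
            }
            for name, sel in selections.items()
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
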