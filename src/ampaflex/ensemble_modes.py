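"""PCA of Cα coordinate ensembles, mode scaling and morph trajectories.

The decomposition operates on the 3N-dimensional coordinate vectors of an
atom-matched ensemble, by default *without* any prior superposition, so that
rigid rearrangements of one ensemble member relative to the rest appear as
modes rather than being fitted away.  The positional covariance is
normalized by the number of frames M (population convention); the two-frame
identity λ = |d|²/4 pins this choice.

Each principal component can be turned into a closed 20-frame morph
trajectory (mean → +max → −max → mean) whose extreme frames sit at either a
requested target RMSD from the mean or at a variance-weighted scale factor
c·√λ; both amplitude conventions are in use for illustrating receptor
motions (e.g. a dominant mode scaled to 20.0 Å RMSD, minor modes by a bare
scale factor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure_io import AtomMatchedEnsemble, AtomLabel, PairingError, kabsch


@dataclass
class ModeSet:
    """Eigen-system of an ensemble's positional covariance.

    ``eigenvectors`` are unit 3N-vectors (rows), orthonormal, ordered by
    descending eigenvalue (Å²); the trace identity Σλ = mean squared
    frame-to-mean deviation holds by construction.
    """

    atom_labels: list[AtomLabel]
    mean_coords: np.ndarray  # (3N,)
    eigenvalues: np.ndarray  # descending, >= 0
    eigenvectors: np.ndarray  # (n_modes, 3N), unit rows
    n_frames: int

    def __post_init__(self) -> None:
        self.mean_coords = np.asarray(self.mean_coords, float)
        self.eigenvalues = np.asarray(self.eigenvalues, float)
        self.eigenvectors = np.asarray(self.eigenvectors, float)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


@dataclass(frozen=True)
class MorphSpec:
    """How to animate one mode: which, how many frames, how far.

    Exactly one of ``target_rmsd`` (Å, extreme-frame RMSD from the mean) or
    ``scale_factor`` (dimensionless multiplier on the √λ-scaled eigenvector)
    must be given.
    """

    mode_index: int  # 1-based
    n_frames: int = 20
    target_rmsd: float | None = None
    scale_factor: float | None = None
    closed: bool = True

    def __post_init__(self) -> None:
        if self.mode_index < 1:
            raise ValueError("mode_index is 1-based and must be >= 1")
        if (self.target_rmsd is None) == (self.scale_factor is None):
            raise ValueError("give exactly one of target_rmsd or scale_factor")


def _canonical_sign_rows(vecs: np.ndarray) -> np.ndarray:
    out = vecs.copy()
    for i, row in enumerate(out):
        nz = np.nonzero(np.abs(row) > 1e-12)[0]
        if nz.size and row[nz[0]] < 0:
            out[i] = -row
    return out


def ensemble_pca(
    ensemble: AtomMatchedEnsemble, superpose_first: bool = False
) -> ModeSet:
    """Principal component analysis of an atom-matched coordinate ensemble.

    With ``superpose_first`` each frame is iteratively Kabsch-fitted to the
    evolving mean (at most 10 iterations, or until the mean moves by less
    than 1e-6 Å) before decomposition; the default analyses the raw frames
    without alignment.
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    frames = ensemble.frames.copy()  # (M, N, 3)
    M, N, _ = frames.shape
    if superpose_first:
        mean = frames.mean(axis=0)
        for _ in range(10):
            for i in range(M):
                R, t, _ = kabsch(frames[i], mean)
                frames[i] = frames[i] @ R.T + t
            new_mean = frames.mean(axis=0)
            shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
            mean = new_mean
            if shift < 1e-6:
                break
    X = frames.reshape(M, 3 * N)
    mean_vec = X.mean(axis=0)
    Xc = X - mean_vec
    # SVD of the centred data; λ_i = s_i² / M (population covariance).
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / M
    eigenvectors = _canonical_sign_rows(Vt)
    return ModeSet(
        atom_labels=list(ensemble.atom_labels),
        mean_coords=mean_vec,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        n_frames=M,
    )


def rmsd_of_displacement(mode: np.ndarray, scale: float, n_atoms: int) -> float:
    """RMSD produced by displacing a structure by ``scale`` along a unit mode.

    For a unit 3N-vector the per-atom mean squared displacement of
    ``scale * mode`` is scale²/N, hence RMSD = |scale|/√N.
    """
    if n_atoms <= 0:
        raise ValueError("n_atoms must be positive")
    mode = np.asarray(mode, float)
    norm = float(np.linalg.norm(mode))
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"mode must be a unit vector (|mode| = {norm:.3g})")
    return abs(float(scale)) / np.sqrt(n_atoms)


def scale_mode(mode_set: ModeSet, spec: MorphSpec) -> tuple[np.ndarray, float]:
    """Displacement 3N-vector for one mode at the requested amplitude.

    ``target_rmsd`` amplitudes give displacement = rmsd·√N·v̂; ``scale_factor``
    amplitudes use the variance-weighted convention c·√λ·v̂ (achieved RMSD
    c·√(λ/N)).  Returns ``(displacement, achieved_rmsd)``.
    """
    k = spec.mode_index - 1
    if k >= mode_set.n_modes:
        raise ValueError(
            f"mode {spec.mode_index} not available ({mode_set.n_modes} modes)"
        )
    v = mode_set.eigenvectors[k]
    N = mode_set.n_atoms
    if spec.target_rmsd is not None:
        scale = float(spec.target_rmsd) * np.sqrt(N)
    else:
        lam = float(mode_set.eigenvalues[k])
        if lam <= 0.0:
            warnings.warn(
                f"mode {spec.mode_index} has zero variance; "
                "scale_factor amplitude produces no motion",
                stacklevel=2,
            )
        scale = float(spec.scale_factor) * np.sqrt(lam)
    displacement = scale * v
    achieved = 0.0 if scale == 0 else rmsd_of_displacement(v, scale, N)
    return displacement, achieved


def _closed_schedule(n_frames: int) -> np.ndarray:
    """Cosine-eased closed cycle 0 → +1 → −1 → 0 over ``n_frames`` samples.

    The +1 and −1 extremes fall exactly on grid points so that the extreme
    frames of a morph achieve the requested amplitude exactly.
    """
    i1 = max(1, round((n_frames - 1) * 0.25))
    i3 = min(n_frames - 2, max(i1 + 1, round((n_frames - 1) * 0.75)))
    sched = np.empty(n_frames)
    up = np.arange(i1 + 1) / i1
    sched[: i1 + 1] = (1 - np.cos(np.pi * up)) / 2  # 0 -> +1
    swing = np.arange(i3 - i1 + 1) / (i3 - i1)
    sched[i1 : i3 + 1] = np.cos(np.pi * swing)  # +1 -> -1
    down = np.arange(n_frames - i3) / (n_frames - 1 - i3)
    sched[i3:] = -(1 + np.cos(np.pi * down)) / 2  # -1 -> 0
    return sched


def _open_schedule(n_frames: int) -> np.ndarray:
    """Cosine-eased single sweep −1 → +1 over ``n_frames`` samples."""
    u = np.arange(n_frames) / (n_frames - 1)
    return -np.cos(np.pi * u)


def make_morph(mode_set: ModeSet, spec: MorphSpec) -> AtomMatchedEnsemble:
    """Morph trajectory sampling one mode over a closed amplitude cycle.

    The closed form starts and ends at the average conformation and visits
    both extremes (+amplitude and −amplitude) exactly.
    """
    if spec.n_frames < 4:
        raise ValueError("a morph needs at least 4 frames")
    displacement, _ = scale_mode(mode_set, spec)
    sched = (
        _closed_schedule(spec.n_frames) if spec.closed else _open_schedule(spec.n_frames)
    )
    frames = mode_set.mean_coords[None, :] + sched[:, None] * displacement[None, :]
    return AtomMatchedEnsemble(
        atom_labels=list(mode_set.atom_labels),
        frames=frames.reshape(spec.n_frames, mode_set.n_atoms, 3),
    )


def cosine_overlap(modes_a: ModeSet, modes_b: ModeSet, k: int) -> np.ndarray:
    """k×k matrix of absolute cosine overlaps |v̂ᵢ·ŵⱼ| between two mode sets."""
    if modes_a.atom_labels != modes_b.atom_labels:
        raise PairingError("mode sets are defined over different atom labels")
    if k < 1 or k > min(modes_a.n_modes, modes_b.n_modes):
        raise ValueError(f"k={k} exceeds available modes")
    return np.abs(modes_a.eigenvectors[:k] @ modes_b.eigenvectors[:k].T)
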