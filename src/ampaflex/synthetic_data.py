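"""Ground-truth generators for every input the analysis pipeline consumes.

Three families of synthetic data are produced, each with its planted
parameters recorded so that recovery can be checked end to end:

* **Tetramer scaffolds** — a four-chain dummy receptor built from helical
  Cα traces: a lower "LBD" body per chain (containing an 11-residue
  "helix G" segment and a single anchor residue at the start of the
  S1–M1-linker position), and an upper "NTD" body per chain, paired into
  two dimers.  The scaffold is exactly two-fold symmetric about z.  Planted
  motions tilt each NTD dimer rigidly about a hinge at its lower tip and
  rotate flagged chains' LBD bodies about the vertical axis through their
  anchor, then add isotropic Gaussian coordinate noise.
* **Classification label sets** — particles drawn swapped with a planted
  probability, partitioned into k classes per run with a planted label
  noise; replicates share the particle ground truth and differ only in
  their RNG stream.
* **Current sweeps** — conditioning pulses with bi-exponential
  desensitization decay, two-pulse recovery protocols with exponential
  peak-ratio recovery, and 20 Hz trains with geometric per-pulse depression.

Domains are rigid point bodies (helical dummy Cα traces) with no side
chains and no physics — sufficient for the COM/axis/angle analyses the
pipeline performs.  All generators are fully deterministic for a given
seed; sub-streams are derived per particle/frame via numpy SeedSequence
spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .class_consensus import ClassificationRun
from .kinetics import SweepTrace
from .structure_io import (
    DomainSelection,
    SelectionMember,
    StructureModel,
)

AC_CHAINS = ("A", "C")
BD_CHAINS = ("B", "D")
CHAINS = ("A", "B", "C", "D")

# residue numbering inside every chain of the scaffold
LBD_RANGE = (1, 30)
HELIX_G_RANGE = (10, 20)  # 11 residues, part of the LBD body
ANCHOR_RESID = 60
NTD_RANGE = (101, 124)


@dataclass(frozen=True)
class ScaffoldGeometry:
    """Dimensions (Å) of the synthetic tetramer scaffold.

    Defaults are receptor-like: an NTD layer ~60 Å above an LBD layer,
    anchor residues on a wider ring below the LBD bodies so that the
    helix-G lever arm about the anchor axis is ~8 Å.
    """

    n_res_lbd: int = 30
    n_res_ntd: int = 24
    lbd_radius: float = 10.0
    anchor_radius: float = 22.0
    ntd_dimer_radius: float = 13.0
    ntd_protomer_offset: float = 16.0
    z_lbd: float = 25.0
    z_anchor: float = 12.0
    z_ntd: float = 62.0
    helix_rise: float = 1.5
    helix_radius: float = 2.3

    def __post_init__(self) -> None:
        if min(self.lbd_radius, self.anchor_radius, self.ntd_dimer_radius) <= 0:
            raise ValueError("scaffold radii must be positive (degenerate geometry)")
        if self.n_res_lbd < HELIX_G_RANGE[1] or self.n_res_ntd < 3:
            raise ValueError("domain sizes too small for the fixed residue layout")


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters for one synthetic dataset.

    Angles in degrees, times in ms, coordinate noise in Å.  ``lbd_rotation``
    maps chain id -> planted rotation about that chain's vertical anchor
    axis; chains absent from the map stay put.
    """

    splay_a: float = 0.0
    splay_b: float = 0.0
    lbd_rotation: dict = field(default_factory=dict)
    swapped_fraction: float = 0.2
    label_noise: float = 0.05
    junk_fraction: float = 0.0
    tau_f: float = 4.0
    tau_s: float = 40.0
    A_f: float = -300.0
    A_s: float = -100.0
    tau_rec: float = 192.0
    r0: float = 0.05
    depression: float = 0.8
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (("splay_a", self.splay_a), ("splay_b", self.splay_b)):
            if not (0.0 <= value <= 180.0):
                raise ValueError(f"{name}={value} outside [0, 180] degrees")
        for chain, angle in self.lbd_rotation.items():
            if not (0.0 <= angle <= 180.0):
                raise ValueError(
                    f"lbd_rotation[{chain!r}]={angle} outside [0, 180] degrees"
                )
        for name, value in (
            ("swapped_fraction", self.swapped_fraction),
            ("label_noise", self.label_noise),
            ("junk_fraction", self.junk_fraction),
        ):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def tau_w(self) -> float:
        total = self.A_f + self.A_s
        return self.tau_f * self.A_f / total + self.tau_s * self.A_s / total


# ---------------------------------------------------------------------------
# scaffold construction


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def _helix(n_res: int, rise: float, radius: float, center: np.ndarray) -> np.ndarray:
    """Vertical dummy Cα helix of n_res residues centred at ``center``."""
    i = np.arange(n_res, dtype=float)
    phi = np.radians(100.0) * i  # canonical ~100° turn per residue
    z = rise * (i - (n_res - 1) / 2.0)
    xyz = np.column_stack([radius * np.cos(phi), radius * np.sin(phi), z])
    return xyz + np.asarray(center, float)


def build_scaffold(geometry: ScaffoldGeometry | None = None) -> StructureModel:
    """Reference tetramer scaffold, exactly two-fold symmetric about z.

    Chains A and B carry the LBD bodies, anchors and NTD protomers; chains
    C and D are their images under a 180° rotation about the global z axis,
    so A/C and B/D form the two symmetry-related pairs.  NTD protomers A and
    B form dimer "a" (B is A's image under the dimer's own two-fold axis),
    C and D form dimer "b".
    """
    g = geometry or ScaffoldGeometry()
    per_chain: dict[str, dict[str, np.ndarray]] = {}

    # chains A (azimuth 0°) and B (azimuth 90°); C, D are the two-fold images
    for chain, azim in (("A", 0.0), ("B", 90.0)):
        Rz = _rot_z(azim)
        lbd_center = Rz @ np.array([g.lbd_radius, 0.0, g.z_lbd])
        anchor = Rz @ np.array([g.anchor_radius, 0.0, g.z_anchor])
        per_chain[chain] = {
            "lbd": _helix(g.n_res_lbd, g.helix_rise, g.helix_radius, lbd_center),
            "anchor": anchor[None, :],
        }

    # NTD dimer "a" (chains A, B) centred at azimuth 45°; protomer B is the
    # image of protomer A under a 180° rotation about the dimer's own
    # vertical two-fold axis, which makes that axis an exact eigenvector of
    # the dimer's positional covariance.
    dimer_center = _rot_z(45.0) @ np.array([g.ntd_dimer_radius, 0.0, g.z_ntd])
    tangent = _rot_z(45.0) @ np.array([0.0, 1.0, 0.0])
    protomer_a = _helix(
        g.n_res_ntd,
        g.helix_rise,
        g.helix_radius,
        dimer_center + g.ntd_protomer_offset * tangent,
    )
    Rz180 = _rot_z(180.0)
    protomer_b = (protomer_a - dimer_center) @ Rz180.T + dimer_center
    per_chain["A"]["ntd"] = protomer_a
    per_chain["B"]["ntd"] = protomer_b

    # global two-fold: C, D are images of A, B
    for src, dst in (("A", "C"), ("B", "D")):
        per_chain[dst] = {part: xyz @ Rz180.T for part, xyz in per_chain[src].items()}

    chain_ids: list[str] = []
    res_numbers: list[int] = []
    res_names: list[str] = []
    atom_names: list[str] = []
    coords: list[np.ndarray] = []

    def add(chain: str, start_res: int, name: str, xyz: np.ndarray) -> None:
        for j, pos in enumerate(xyz):
            chain_ids.append(chain)
            res_numbers.append(start_res + j)
            res_names.append(name)
            atom_names.append("CA")
            coords.append(pos)

    for chain in CHAINS:
        parts = per_chain[chain]
        add(chain, LBD_RANGE[0], "GLY", parts["lbd"])
        add(chain, ANCHOR_RESID, "LYS", parts["anchor"])
        add(chain, NTD_RANGE[0], "ALA", parts["ntd"])

    return StructureModel(
        model_id="scaffold_ref",
        chain_ids=np.array(chain_ids, dtype=object),
        residue_numbers=np.array(res_numbers, dtype=int),
        residue_names=np.array(res_names, dtype=object),
        atom_names=np.array(atom_names, dtype=object),
        coords=np.array(coords, dtype=float),
    )


def dimer_chains(dimer_id: str) -> tuple[str, str]:
    return {"a": ("A", "B"), "b": ("C", "D")}[dimer_id]


def dimer_hinge(dimer_id: str, geometry: ScaffoldGeometry | None = None) -> np.ndarray:
    """Hinge point of an NTD dimer: its lower tip, on the dimer axis.

    Mimics the NTD–LBD linker attachment; planted tilts rotate the dimer
    rigidly about this point.
    """
    g = geometry or ScaffoldGeometry()
    azim = {"a": 45.0, "b": 225.0}[dimer_id]
    z_bottom = g.z_ntd - g.helix_rise * (g.n_res_ntd - 1) / 2.0 - g.helix_rise
    return _rot_z(azim) @ np.array([g.ntd_dimer_radius, 0.0, z_bottom])


def dimer_tilt_axis(dimer_id: str) -> np.ndarray:
    """Horizontal tilt axis (ẑ × outward radial direction) of a dimer."""
    azim = {"a": 45.0, "b": 225.0}[dimer_id]
    u = _rot_z(azim) @ np.array([1.0, 0.0, 0.0])
    return np.cross(np.array([0.0, 0.0, 1.0]), u)


def default_selections(
    geometry: ScaffoldGeometry | None = None,
) -> dict[str, DomainSelection]:
    """Named selections matching the scaffold's fixed residue layout."""
    g = geometry or ScaffoldGeometry()
    lbd_end = LBD_RANGE[0] + g.n_res_lbd - 1
    ntd_end = NTD_RANGE[0] + g.n_res_ntd - 1

    def span(chains, start, end, atom=None):
        return tuple(
            SelectionMember(chain_id=c, res_start=start, res_end=end, atom_name=atom)
            for c in chains
        )

    return {
        "dimer_a": DomainSelection(
            "dimer_a", span(("A", "B"), NTD_RANGE[0], ntd_end), role="ntd_dimer"
        ),
        "dimer_b": DomainSelection(
            "dimer_b", span(("C", "D"), NTD_RANGE[0], ntd_end), role="ntd_dimer"
        ),
        "receptor": DomainSelection(
            "receptor", span(CHAINS, 1, max(ANCHOR_RESID, ntd_end)),
            role="reference_body",
        ),
        "anchors": DomainSelection(
            "anchors", span(CHAINS, ANCHOR_RESID, ANCHOR_RESID), role="anchor_residue"
        ),
        "helix_g": DomainSelection(
            "helix_g", span(CHAINS, HELIX_G_RANGE[0], HELIX_G_RANGE[1]), role="helix_g"
        ),
        "lbd_bodies": DomainSelection(
            "lbd_bodies", span(CHAINS, LBD_RANGE[0], lbd_end), role="lbd_subunit"
        ),
    }


def apply_planted_motion(
    reference: StructureModel,
    truth: GroundTruth,
    geometry: ScaffoldGeometry | None = None,
    model_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> StructureModel:
    """Plant NTD dimer tilts and LBD rotations on a scaffold, then add noise.

    Each NTD dimer is rotated rigidly by its planted angle about the
    horizontal axis through its hinge point (tilting the dimer outward);
    each chain listed in ``truth.lbd_rotation`` has its LBD body (including
    helix G and the on-axis anchor) rotated about the vertical axis through
    its anchor.  Isotropic Gaussian coordinate noise is added last.
    """
    g = geometry or ScaffoldGeometry()
    out = reference.copy(model_id=model_id or f"planted_{truth.seed}")
    coords = out.coords

    for dimer_id, angle in (("a", truth.splay_a), ("b", truth.splay_b)):
        if angle == 0.0:
            continue
        hinge = dimer_hinge(dimer_id, g)
        R = rotation_about_axis(dimer_tilt_axis(dimer_id), angle)
        chains = dimer_chains(dimer_id)
        mask = np.isin(out.chain_ids, chains) & (
            (out.residue_numbers >= NTD_RANGE[0])
        )
        coords[mask] = (coords[mask] - hinge) @ R.T + hinge

    for chain, angle in sorted(truth.lbd_rotation.items()):
        if angle == 0.0:
            continue
        anchor_mask = (out.chain_ids == chain) & (out.residue_numbers == ANCHOR_RESID)
        if not anchor_mask.any():
            raise ValueError(f"chain {chain!r} has no anchor residue")
        axis_point = coords[anchor_mask].mean(axis=0)
        R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), angle)
        body = (out.chain_ids == chain) & (
            (out.residue_numbers <= LBD_RANGE[0] + g.n_res_lbd - 1)
            | (out.residue_numbers == ANCHOR_RESID)
        )
        coords[body] = (coords[body] - axis_point) @ R.T + axis_point

    if truth.noise_sigma > 0:
        rng = rng or np.random.default_rng(truth.seed)
        coords += rng.normal(0.0, truth.noise_sigma, coords.shape)
    out.coords = coords
    return out


def simulate_ensemble(
    n_models: int = 12,
    max_splay: float = 60.0,
    noise_sigma: float = 0.2,
    seed: int = 0,
    geometry: ScaffoldGeometry | None = None,
) -> tuple[StructureModel, list[StructureModel], pd.DataFrame]:
    """Reference scaffold plus models with random planted splay angles.

    Splay angles are drawn uniformly from [0, max_splay] degrees per dimer;
    coordinate noise defaults to 0.2 Å.  Returns (reference, models,
    ground-truth table).
    """
    g = geometry or ScaffoldGeometry()
    reference = build_scaffold(g)
    rng = np.random.default_rng(seed)
    models = []
    truth_rows = []
    for i in range(n_models):
        a, b = rng.uniform(0.0, max_splay, size=2)
        truth = GroundTruth(
            splay_a=float(a), splay_b=float(b), noise_sigma=noise_sigma, seed=seed
        )
        model = apply_planted_motion(
            reference, truth, g, model_id=f"model_{i:03d}", rng=rng
        )
        models.append(model)
        truth_rows.append(
            {
                "model_id": model.model_id,
                "splay_a_deg": float(a),
                "splay_b_deg": float(b),
                "noise_sigma_A": noise_sigma,
                "seed": seed,
            }
        )
    return reference, models, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# classification runs


def simulate_classifications(
    n_particles: int,
    truth: GroundTruth,
    k_list,
    n_replicates: int = 3,
    seed: int | None = None,
) -> list[ClassificationRun]:
    """Replicated particle classifications with a planted swapped fraction.

    Particle ground truth (category and a latent within-category score) is
    drawn once and shared by every run, so replicate runs co-migrate
    strongly; with probability ``label_noise`` a particle is scattered to a
    uniformly random class of the run instead of the class its category and
    latent score determine.  Class categories split each run's k classes
    proportionally to the planted fraction (at least one class per
    category).
    """
    seed = truth.seed if seed is None else seed
    k_list = list(k_list)
    if min(k_list) < 3:
        raise ValueError("k must be >= 3")
    if max(k_list) > n_particles:
        raise ValueError("k exceeds the number of particles")
    root = np.random.SeedSequence(seed)
    particle_ss, *run_ss = root.spawn(1 + len(k_list) * n_replicates)
    prng = np.random.default_rng(particle_ss)

    u = prng.uniform(size=n_particles)
    is_junk = u < truth.junk_fraction
    is_swapped = (~is_junk) & (
        u < truth.junk_fraction + (1 - truth.junk_fraction) * truth.swapped_fraction
    )
    latent = prng.uniform(size=n_particles)  # within-category class position

    runs: list[ClassificationRun] = []
    stream = iter(run_ss)
    for k in k_list:
        n_junk_classes = 1 if truth.junk_fraction > 0 else 0
        k_eff = k - n_junk_classes
        k_swapped = int(np.clip(round(k_eff * truth.swapped_fraction), 1, k_eff - 1))
        class_ids = [f"c{j:02d}" for j in range(k)]
        categories = {}
        swapped_classes, nonswapped_classes, junk_classes = [], [], []
        for j, cid in enumerate(class_ids):
            if j < k_swapped:
                categories[cid] = "swapped"
                swapped_classes.append(cid)
            elif j < k_eff:
                categories[cid] = "non_swapped"
                nonswapped_classes.append(cid)
            else:
                categories[cid] = "junk"
                junk_classes.append(cid)
        pools = {
            "swapped": swapped_classes,
            "non_swapped": nonswapped_classes,
            "junk": junk_classes or nonswapped_classes,
        }
        for rep in range(n_replicates):
            rng = np.random.default_rng(next(stream))
            scatter = rng.uniform(size=n_particles) < truth.label_noise
            random_class = rng.integers(0, k, size=n_particles)
            labels = {}
            for p in range(n_particles):
                if scatter[p]:
                    cid = class_ids[random_class[p]]
                else:
                    if is_junk[p]:
                        pool = pools["junk"]
                    elif is_swapped[p]:
                        pool = pools["swapped"]
                    else:
                        pool = pools["non_swapped"]
                    cid = pool[min(int(latent[p] * len(pool)), len(pool) - 1)]
                labels[f"p{p:06d}"] = cid
            runs.append(
                ClassificationRun(
                    run_id=f"k{k:02d}_rep{rep}",
                    k=k,
                    labels=labels,
                    class_categories=categories,
                )
            )
    return runs


# ---------------------------------------------------------------------------
# current sweeps


def _pulse_current(
    t: np.ndarray,
    onset: float,
    duration: float,
    peak_scale: float,
    truth: GroundTruth,
) -> np.ndarray:
    """Ideal desensitizing current for one agonist pulse (no noise).

    Instantaneous rise at onset, decay I(t) = I_ss + A_f·e^(−t/τf) +
    A_s·e^(−t/τs) with a steady state of 5 % of the summed amplitudes, and
    fast deactivation (1 ms) after pulse end.  The planted amplitudes are
    the exponential coefficients at the peak time, matching the convention
    of the decay fitter.
    """
    current = np.zeros_like(t)
    i_ss = 0.05 * (truth.A_f + truth.A_s)
    inside = (t >= onset) & (t < onset + duration)
    td = t[inside] - onset
    current[inside] = peak_scale * (
        i_ss
        + truth.A_f * np.exp(-td / truth.tau_f)
        + truth.A_s * np.exp(-td / truth.tau_s)
    )
    after = t >= onset + duration
    if after.any() and inside.any():
        i_end = current[inside][-1]
        current[after] = i_end * np.exp(-(t[after] - (onset + duration)) / 1.0)
    return current


def simulate_decay_sweep(
    truth: GroundTruth,
    pulse_duration: float = 100.0,
    sampling_khz: float = 100.0,
    noise_frac: float = 0.0,
    seed: int | None = None,
) -> SweepTrace:
    """Single conditioning-pulse sweep with planted bi-exponential decay.

    Additive Gaussian noise has SD ``noise_frac`` × |peak|.  Baseline spans
    the 10 ms before pulse onset.
    """
    seed = truth.seed if seed is None else seed
    dt = 1.0 / sampling_khz
    onset, tail = 10.0, 20.0
    t = np.arange(0.0, onset + pulse_duration + tail, dt)
    current = _pulse_current(t, onset, pulse_duration, 1.0, truth)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(
            0.0, noise_frac * abs(truth.A_f + truth.A_s), t.shape
        )
    return SweepTrace(
        time=t,
        current=current,
        protocol=[(onset, pulse_duration)],
        baseline_window=(0.0, onset - dt),
    )


def simulate_recovery_sweeps(
    truth: GroundTruth,
    intervals=None,
    conditioning_ms: float = 100.0,
    test_ms: float = 10.0,
    sampling_khz: float = 5.0,
    noise_frac: float = 0.0,
    seed: int | None = None,
) -> list[SweepTrace]:
    """Two-pulse recovery protocol: one sweep per inter-pulse interval.

    The test-pulse peak is scaled by 1 − (1 − r₀)·exp(−Δt/τ_rec) where Δt is
    the interval from conditioning-pulse end to test-pulse onset (default
    intervals 20–1500 ms in 20 ms steps).
    """
    seed = truth.seed if seed is None else seed
    if intervals is None:
        intervals = np.arange(20.0, 1501.0, 20.0)
    intervals = np.asarray(intervals, float)
    if np.any(intervals <= 0):
        raise ValueError("intervals must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_khz
    onset = 10.0
    sweeps = []
    peak = abs(truth.A_f + truth.A_s)
    for interval in intervals:
        test_onset = onset + conditioning_ms + interval
        t = np.arange(0.0, test_onset + test_ms + 10.0, dt)
        recovery = 1.0 - (1.0 - truth.r0) * np.exp(-interval / truth.tau_rec)
        current = _pulse_current(t, onset, conditioning_ms, 1.0, truth)
        current += _pulse_current(t, test_onset, test_ms, recovery, truth)
        if noise_frac > 0:
            current = current + rng.normal(0.0, noise_frac * peak, t.shape)
        sweeps.append(
            SweepTrace(
                time=t,
                current=current,
                protocol=[(onset, conditioning_ms), (test_onset, test_ms)],
                baseline_window=(0.0, onset - dt),
            )
        )
    return sweeps


def simulate_train_peaks(
    truth: GroundTruth, n_pulses: int = 10, stim_freq: float = 20.0
) -> np.ndarray:
    """Peak amplitudes of a stimulus train with geometric depression.

    Pulse i has amplitude (A_f + A_s) · depression**i; frequency is
    metadata only (the depression factor is per pulse).
    """
    if n_pulses < 2:
        raise ValueError("a train needs >= 2 pulses")
    first = truth.A_f + truth.A_s
    return first * truth.depression ** np.arange(n_pulses, dtype=float)


def truth_to_dict(truth: GroundTruth) -> dict:
    """Plain-dict form of a ground truth record (for YAML/JSON sidecars)."""
    return {
        "splay_a_deg": truth.splay_a,
        "splay_b_deg": truth.splay_b,
        "lbd_rotation_deg": dict(truth.lbd_rotation),
        "swapped_fraction": truth.swapped_fraction,
        "label_noise": truth.label_noise,
        "junk_fraction": truth.junk_fraction,
        "tau_f_ms": truth.tau_f,
        "tau_s_ms": truth.tau_s,
        "A_f_pA": truth.A_f,
        "A_s_pA": truth.A_s,
        "tau_rec_ms": truth.tau_rec,
        "r0": truth.r0,
        "depression": truth.depression,
        "noise_sigma_A": truth.noise_sigma,
        "seed": truth.seed,
    }
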