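"""Synthetic inputs with planted ground truth for every pipeline stage.

These generators emulate the shapes of data the analysis consumes — toy
protein topologies with an optional heme/substrate pair, trajectory ensembles
with planted low-rank covariance modes, metastable-state mixtures of
controllable overlap, hydrogen-bond scenarios with per-condition occupancy
schedules, substrate-coupled trajectories with a planted correlation, and
noisy spectroscopic curves — so that every stage can be tested against known
truth without running molecular dynamics. Each generator takes a mandatory
seed, draws from a single pseudo-random stream, and returns its ground truth
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import (
    AtomRecord,
    Topology,
    TrajectoryEnsemble,
)

# ---------------------------------------------------------------------------
# Toy topology
# ---------------------------------------------------------------------------

_BACKBONE_TEMPLATE = (
    ("N", "N", (0.00, 0.00, 0.00)),
    ("CA", "C", (1.46, 1.00, 0.30)),
    ("C", "C", (2.60, 0.00, 0.10)),
    ("O", "O", (2.60, -1.23, 0.20)),
)
_SIDECHAIN_TEMPLATE = (
    ("OG", "O", (1.46, 2.40, 0.70)),  # relative to residue origin (CA + (0,1.4,0.4))
    ("HG", "H", (2.42, 2.40, 0.70)),
)
_RESIDUE_SPACING = 3.8  # Å along x


@dataclass
class ToyStructure:
    """A generated topology plus reference coordinates and bookkeeping.

    ``advertised_count`` recounts atoms for a selection directly from the
    construction records, independently of :func:`peroxidyn.select_atoms`,
    so it can serve as an oracle for selection tests. ``donor_pairs`` and
    ``acceptor_indices`` list the hydrogen-bond-capable atoms by
    construction.
    """

    topology: Topology
    coordinates: np.ndarray  # (N, 3) reference frame, Å
    donor_pairs: list[tuple[int, int]] = field(default_factory=list)
    acceptor_indices: list[int] = field(default_factory=list)
    fe_index: int | None = None
    substrate_calpha_index: int | None = None
    substrate_cbeta_index: int | None = None

    def advertised_count(
        self,
        residue_range: tuple[int, int] | None = None,
        backbone_only: bool = False,
        include_residue_names: set[str] | None = None,
        exclude_hydrogens: bool = False,
    ) -> int:
        count = 0
        for atom in self.topology.atoms:
            in_extra = (
                include_residue_names is not None
                and atom.residue_name in include_residue_names
            )
            in_primary = True
            if residue_range is not None and not (
                residue_range[0] <= atom.residue_id <= residue_range[1]
            ):
                in_primary = False
            if backbone_only and (
                atom.is_hetero or atom.name not in ("N", "CA", "C", "O")
            ):
                in_primary = False
            if not (residue_range is not None or backbone_only):
                in_primary = include_residue_names is None
            if not (in_primary or in_extra):
                continue
            if exclude_hydrogens and atom.is_hydrogen:
                continue
            count += 1
        return count


def build_toy_topology(
    n_residues: int,
    with_cofactors: bool = False,
    polar_sidechains: bool = False,
    residue_names: list[str] | None = None,
    chain_id: str = "A",
) -> ToyStructure:
    """Linear toy peptide with optional serine-like sidechains and cofactors.

    Each residue carries an N/CA/C/O backbone along a 3.8 Å-spaced chain;
    ``polar_sidechains`` adds an OG/HG hydroxyl pair (a donor) per residue.
    ``with_cofactors`` appends a heme group (HEM, containing a single FE and
    two propionate oxygens) and a truncated fatty-acid substrate (PLM, with
    carboxylate oxygens and atoms named CA/CB for the substrate Cα and Cβ).
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if residue_names is None:
        residue_names = ["SER" if polar_sidechains else "ALA"] * n_residues
    if len(residue_names) != n_residues:
        raise ValueError("residue_names length must equal n_residues")

    atoms: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []
    donor_pairs: list[tuple[int, int]] = []
    acceptors: list[int] = []
    serial = 1

    def add_atom(name, element, xyz, resname, resid, hetero):
        nonlocal serial
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                element=element,
                residue_name=resname,
                residue_id=resid,
                chain_id=chain_id,
                is_hetero=hetero,
                coordinates=tuple(float(v) for v in xyz),
            )
        )
        coords.append(tuple(float(v) for v in xyz))
        if element in ("N", "O") and not name.startswith("H"):
            acceptors.append(len(atoms) - 1)
        serial += 1
        return len(atoms) - 1

    for i in range(n_residues):
        x0 = i * _RESIDUE_SPACING
        resid = i + 1
        resname = residue_names[i]
        for name, element, offset in _BACKBONE_TEMPLATE:
            add_atom(name, element, (x0 + offset[0], offset[1], offset[2]),
                     resname, resid, False)
        if polar_sidechains:
            og = add_atom(
                "OG", "O",
                (x0 + _SIDECHAIN_TEMPLATE[0][2][0],
                 _SIDECHAIN_TEMPLATE[0][2][1], _SIDECHAIN_TEMPLATE[0][2][2]),
                resname, resid, False,
            )
            hg = add_atom(
                "HG", "H",
                (x0 + _SIDECHAIN_TEMPLATE[1][2][0],
                 _SIDECHAIN_TEMPLATE[1][2][1], _SIDECHAIN_TEMPLATE[1][2][2]),
                resname, resid, False,
            )
            donor_pairs.append((og, hg))

    fe_index = sub_ca = sub_cb = None
    if with_cofactors:
        cx = (n_residues - 1) * _RESIDUE_SPACING / 2.0
        heme_id = n_residues + 1
        fe_index = add_atom("FE", "FE", (cx, 6.0, 0.0), "HEM", heme_id, True)
        for name, offset in (
            ("NA", (2.0, 0.0, 0.0)), ("NB", (-2.0, 0.0, 0.0)),
            ("NC", (0.0, 2.0, 0.0)), ("ND", (0.0, -2.0, 0.0)),
        ):
            add_atom(name, "N", (cx + offset[0], 6.0 + offset[1], offset[2]),
                     "HEM", heme_id, True)
        add_atom("O1A", "O", (cx + 3.0, 8.0, 0.5), "HEM", heme_id, True)
        add_atom("O2A", "O", (cx + 3.6, 8.6, -0.3), "HEM", heme_id, True)

        plm_id = n_residues + 2
        cb_xyz = np.array([cx, 6.0, 4.2])
        ca_xyz = cb_xyz + np.array([1.5, 0.0, 0.5])
        c1_xyz = ca_xyz + np.array([1.5, 0.0, 0.0])
        sub_cb = add_atom("CB", "C", cb_xyz, "PLM", plm_id, True)
        sub_ca = add_atom("CA", "C", ca_xyz, "PLM", plm_id, True)
        add_atom("C1", "C", c1_xyz, "PLM", plm_id, True)
        add_atom("O1", "O", c1_xyz + np.array([0.6, 1.0, 0.0]), "PLM", plm_id, True)
        add_atom("O2", "O", c1_xyz + np.array([0.6, -1.0, 0.0]), "PLM", plm_id, True)

    return ToyStructure(
        topology=Topology(atoms),
        coordinates=np.asarray(coords, dtype=float),
        donor_pairs=donor_pairs,
        acceptor_indices=acceptors,
        fe_index=fe_index,
        substrate_calpha_index=sub_ca,
        substrate_cbeta_index=sub_cb,
    )


# ---------------------------------------------------------------------------
# Planted covariance modes
# ---------------------------------------------------------------------------

@dataclass
class ModeSpec:
    """Planted low-rank covariance structure for mode trajectories.

    ``mode_vectors`` (k, 3N) must be mutually orthonormal; ``amplitudes`` are
    the per-mode standard deviations in Å, strictly decreasing so the PC
    order is unambiguous in recovery tests.
    """

    mode_vectors: np.ndarray
    amplitudes: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self):
        self.mode_vectors = np.atleast_2d(np.asarray(self.mode_vectors, float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, float))
        k = self.mode_vectors.shape[0]
        if self.amplitudes.shape != (k,):
            raise ValueError("one amplitude per mode vector required")
        gram = self.mode_vectors @ self.mode_vectors.T
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValueError("mode vectors must be mutually orthonormal")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative")
        positive = self.amplitudes[self.amplitudes > 0]
        if positive.size > 1 and not np.all(np.diff(positive) < 0):
            raise ValueError("amplitudes must be strictly decreasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def random_orthonormal_modes(dim: int, k: int, seed: int) -> np.ndarray:
    """k mutually orthonormal random directions in R^dim (QR construction)."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((dim, k)))
    return q.T


@dataclass
class ModeTrajectoryTruth:
    mode_vectors: np.ndarray
    amplitudes: np.ndarray
    noise_sd: float
    coefficients: np.ndarray  # (F, k) mode coefficients actually drawn


def generate_mode_trajectory(
    topology: Topology,
    reference: np.ndarray,
    modes: ModeSpec,
    n_frames: int,
    seed: int,
    condition: str = "default",
    temperature_c: float | None = None,
    coefficients: np.ndarray | None = None,
) -> tuple[TrajectoryEnsemble, ModeTrajectoryTruth]:
    """Frames = reference + Σ_m a_m(t)·mode_m + isotropic noise.

    Coefficients a_m(t) are Normal(0, amplitude_m²) unless given explicitly
    (e.g. to force a two-frame ±1 instance with a known decomposition).
    """
    reference = np.asarray(reference, dtype=float)
    dim = reference.size
    if modes.mode_vectors.shape[1] != dim:
        raise ValueError(
            f"mode vectors have dimension {modes.mode_vectors.shape[1]}, "
            f"expected 3N = {dim}"
        )
    rng = np.random.default_rng(seed)
    if coefficients is None:
        coefficients = rng.normal(
            0.0, modes.amplitudes, size=(n_frames, modes.amplitudes.size)
        )
    else:
        coefficients = np.asarray(coefficients, dtype=float)
        if coefficients.shape != (n_frames, modes.amplitudes.size):
            raise ValueError("coefficients must be (n_frames, n_modes)")
    flat = reference.ravel()[None, :] + coefficients @ modes.mode_vectors
    if modes.noise_sd > 0:
        flat = flat + rng.normal(0.0, modes.noise_sd, size=flat.shape)
    frames = flat.reshape(n_frames, -1, 3)
    ensemble = TrajectoryEnsemble.from_frames(
        topology, frames, condition, temperature_c
    )
    truth = ModeTrajectoryTruth(
        modes.mode_vectors.copy(), modes.amplitudes.copy(), modes.noise_sd,
        coefficients,
    )
    return ensemble, truth


# ---------------------------------------------------------------------------
# Metastable states
# ---------------------------------------------------------------------------

@dataclass
class StatePlan:
    """Planted conformational states: centers, populations, spread, overlap.

    ``overlap_factor`` scales every center's separation from the centroid of
    the centers: 1 keeps the planted geometry, values toward 0 collapse the
    states into a single effective cluster (the "elongated, partially
    overlapping" regime), values above 1 separate them further.
    """

    state_centers: np.ndarray  # (K, N, 3)
    frames_per_state: np.ndarray
    within_state_sd: float
    overlap_factor: float = 1.0

    def __post_init__(self):
        self.state_centers = np.asarray(self.state_centers, dtype=float)
        self.frames_per_state = np.atleast_1d(
            np.asarray(self.frames_per_state, dtype=int)
        )
        if self.state_centers.ndim != 3 or self.state_centers.shape[0] < 1:
            raise ValueError("state_centers must be (K, N, 3) with K >= 1")
        if self.frames_per_state.shape[0] != self.state_centers.shape[0]:
            raise ValueError("one frame count per state required")
        if np.any(self.frames_per_state < 1):
            raise ValueError("each state needs at least one frame")
        if self.within_state_sd < 0:
            raise ValueError("within_state_sd must be nonnegative")

    def effective_centers(self) -> np.ndarray:
        centroid = self.state_centers.mean(axis=0, keepdims=True)
        return centroid + self.overlap_factor * (self.state_centers - centroid)


def make_state_plan(
    reference: np.ndarray,
    n_states: int,
    frames_per_state: int,
    separation: float,
    within_state_sd: float,
    seed: int,
    overlap_factor: float = 1.0,
) -> StatePlan:
    """Plant K states along orthonormal collective directions.

    ``separation`` is the Cartesian RMSD (Å) of each state center from the
    reference structure — the same per-atom scale as ``within_state_sd`` —
    so "separation 10× the within-state sd" keeps its meaning regardless of
    the atom count. Centers planted along orthonormal directions are
    pairwise √2·separation apart.
    """
    reference = np.asarray(reference, dtype=float)
    directions = random_orthonormal_modes(reference.size, n_states, seed)
    scale = separation * np.sqrt(reference.shape[0])
    centers = reference[None, :, :] + scale * directions.reshape(
        n_states, *reference.shape
    )
    return StatePlan(
        state_centers=centers,
        frames_per_state=np.full(n_states, frames_per_state),
        within_state_sd=within_state_sd,
        overlap_factor=overlap_factor,
    )


def generate_metastable_ensemble(
    topology: Topology,
    plan: StatePlan,
    seed: int,
    condition: str = "default",
    temperature_c: float | None = None,
) -> tuple[TrajectoryEnsemble, np.ndarray]:
    """Draw frames around each planted state center; returns true labels."""
    rng = np.random.default_rng(seed)
    centers = plan.effective_centers()
    frames = []
    labels = []
    for k in range(centers.shape[0]):
        n_k = int(plan.frames_per_state[k])
        jitter = rng.normal(0.0, plan.within_state_sd, size=(n_k, *centers[k].shape))
        frames.append(centers[k][None] + jitter)
        labels.extend([k] * n_k)
    ensemble = TrajectoryEnsemble.from_frames(
        topology, np.concatenate(frames, axis=0), condition, temperature_c
    )
    return ensemble, np.asarray(labels, dtype=int)


# ---------------------------------------------------------------------------
# Hydrogen-bond scenarios
# ---------------------------------------------------------------------------

@dataclass
class HBondPlan:
    """Planted donor/hydrogen/acceptor triads with per-condition occupancies.

    ``bound_geometry``/``unbound_geometry`` are (donor–acceptor distance Å,
    D–H–A deviation from linearity °) applied when a triad is "on"/"off";
    the bound geometry must satisfy the detection cutoffs and the unbound
    geometry must violate at least one of them.
    """

    triads: list[tuple[int, int, int]]
    occupancy_by_condition: dict  # label -> sequence of fractions per triad
    bound_geometry: tuple[float, float] = (2.8, 0.0)
    unbound_geometry: tuple[float, float] = (4.5, 0.0)
    distance_cutoff: float = 3.0
    angle_cutoff: float = 20.0

    def __post_init__(self):
        acceptors = [a for (_, _, a) in self.triads]
        if len(set(acceptors)) != len(acceptors):
            raise ValueError("triads must not share acceptor atoms")
        for label, occs in self.occupancy_by_condition.items():
            occs = np.asarray(occs, dtype=float)
            if occs.shape[0] != len(self.triads):
                raise ValueError(f"condition {label!r}: one occupancy per triad")
            if np.any((occs < 0) | (occs > 1)):
                raise ValueError("occupancies must lie in [0, 1]")
        b_dist, b_dev = self.bound_geometry
        if b_dist > self.distance_cutoff or b_dev > self.angle_cutoff:
            raise ValueError("bound geometry must satisfy the detection cutoffs")
        u_dist, u_dev = self.unbound_geometry
        if u_dist <= self.distance_cutoff and u_dev <= self.angle_cutoff:
            raise ValueError("unbound geometry must violate at least one cutoff")


@dataclass
class HBondScenarioTruth:
    planted_occupancy: dict  # label -> (n_triads,) planted fractions
    realized_on: dict  # label -> (n_frames, n_triads) boolean draws
    triads: list[tuple[int, int, int]]
    residue_pairs: list  # unordered residue-pair key per triad


def _acceptor_position(
    donor: np.ndarray, hydrogen: np.ndarray, distance: float, deviation_deg: float
) -> np.ndarray:
    """Place the acceptor at a given D–A distance and D–H–A deviation."""
    u = hydrogen - donor
    h_len = np.linalg.norm(u)
    u = u / h_len
    if deviation_deg == 0.0:
        return donor + distance * u
    dev = np.radians(deviation_deg)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, u)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    p = np.cross(u, helper)
    p = p / np.linalg.norm(p)
    w = np.cos(dev) * u + np.sin(dev) * p
    t = -h_len * np.cos(dev) + np.sqrt(
        h_len**2 * np.cos(dev) ** 2 - h_len**2 + distance**2
    )
    return hydrogen + t * w


def generate_hbond_scenario(
    topology: Topology,
    reference: np.ndarray,
    plan: HBondPlan,
    n_frames: int,
    seed: int,
    temperatures: dict | None = None,
) -> tuple[dict, HBondScenarioTruth]:
    """Two-condition (or more) ensembles realizing the planted bond schedule.

    Per frame and triad, the bond is independently "on" with its planted
    occupancy; the acceptor atom is moved to the bound or unbound geometry
    along the donor–hydrogen axis accordingly. Returns one ensemble per
    condition plus the truth record (planted fractions and realized draws).
    """
    reference = np.asarray(reference, dtype=float)
    rng = np.random.default_rng(seed)
    ensembles: dict = {}
    realized: dict = {}
    pairs = []
    for d, _, a in plan.triads:
        sides = sorted(
            (
                (t.chain_id, t.residue_id, t.insertion_code, t.residue_name)
                for t in (topology.atoms[d], topology.atoms[a])
            )
        )
        pairs.append(tuple(sides))
    for label in plan.occupancy_by_condition:
        occs = np.asarray(plan.occupancy_by_condition[label], dtype=float)
        on = rng.random(size=(n_frames, len(plan.triads))) < occs[None, :]
        frames = np.repeat(reference[None], n_frames, axis=0)
        for f in range(n_frames):
            for t_idx, (d, h, a) in enumerate(plan.triads):
                geom = plan.bound_geometry if on[f, t_idx] else plan.unbound_geometry
                frames[f, a] = _acceptor_position(
                    frames[f, d], frames[f, h], geom[0], geom[1]
                )
        temp = None if temperatures is None else temperatures.get(label)
        ensembles[label] = TrajectoryEnsemble.from_frames(
            topology, frames, label, temp
        )
        realized[label] = on
    truth = HBondScenarioTruth(
        planted_occupancy={
            label: np.asarray(v, dtype=float)
            for label, v in plan.occupancy_by_condition.items()
        },
        realized_on=realized,
        triads=list(plan.triads),
        residue_pairs=pairs,
    )
    return ensembles, truth


# ---------------------------------------------------------------------------
# Substrate coupling
# ---------------------------------------------------------------------------

@dataclass
class CoupledTrajectoryTruth:
    latent: np.ndarray
    z_true: np.ndarray
    fe_cbeta_distance: np.ndarray
    calpha_cbeta_fe_angle: np.ndarray
    displacement_magnitude: np.ndarray
    coupled_residue_key: tuple
    rho: float


def generate_coupled_substrate_trajectory(
    toy: ToyStructure,
    coupled_residue_id: int,
    rho: float,
    n_frames: int,
    seed: int,
    condition: str = "default",
    temperature_c: float | None = None,
    base_distance: float = 4.5,
    distance_sd: float = 0.4,
    base_angle: float = 110.0,
    angle_sd: float = 6.0,
    displacement_base: float = 1.0,
    displacement_sd: float = 0.2,
    background_noise_sd: float = 0.02,
) -> tuple[TrajectoryEnsemble, CoupledTrajectoryTruth]:
    """Trajectory whose substrate geometry is coupled to one residue's motion.

    A shared standard-normal latent drives both substrate descriptors
    (Fe–Cβ distance and Cα–Cβ–Fe angle vary linearly with it) and, at
    correlation ``rho``, the displacement magnitude of the coupled residue's
    Cα, which moves isotropically about its reference position with magnitude
    ``displacement_base + displacement_sd·(ρ·latent + √(1−ρ²)·noise)``.
    All other atoms receive small independent jitter. The estimated coupling
    r converges to ρ as the frame count grows.
    """
    if not (-1.0 <= rho <= 1.0):
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    if toy.fe_index is None:
        raise ValueError("toy structure must be built with_cofactors=True")
    rng = np.random.default_rng(seed)
    top = toy.topology
    reference = toy.coordinates
    fe = toy.fe_index
    ca = toy.substrate_calpha_index
    cb = toy.substrate_cbeta_index

    latent = rng.standard_normal(n_frames)
    distances = base_distance + distance_sd * latent
    angles = np.clip(base_angle + angle_sd * latent, 1.0, 179.0)

    eps = rng.standard_normal(n_frames)
    magnitudes = displacement_base + displacement_sd * (
        rho * latent + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
    )
    magnitudes = np.clip(magnitudes, 0.01, None)
    directions = rng.standard_normal((n_frames, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)

    coupled_key = None
    coupled_ca = None
    for key, atom_positions in top.residue_index.items():
        if key[1] == coupled_residue_id and not top.atoms[atom_positions[0]].is_hetero:
            for i in atom_positions:
                if top.atoms[i].name == "CA":
                    coupled_key, coupled_ca = key, i
    if coupled_ca is None:
        raise ValueError(f"no CA atom for residue id {coupled_residue_id}")

    fe_pos = reference[fe]
    e1 = reference[cb] - fe_pos
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, e1)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 = e2 / np.linalg.norm(e2)
    r_ca_bond = 1.5

    frames = np.repeat(reference[None], n_frames, axis=0)
    if background_noise_sd > 0:
        noise = rng.normal(0.0, background_noise_sd, size=frames.shape)
        noise[:, [fe, ca, cb, coupled_ca], :] = 0.0
        frames = frames + noise
    for f in range(n_frames):
        cb_pos = fe_pos + e1 * distances[f]
        u = -e1  # unit vector from Cβ toward Fe
        theta = np.radians(angles[f])
        ca_pos = cb_pos + r_ca_bond * (np.cos(theta) * u + np.sin(theta) * e2)
        frames[f, cb] = cb_pos
        frames[f, ca] = ca_pos
        frames[f, fe] = fe_pos
        frames[f, coupled_ca] = reference[coupled_ca] + magnitudes[f] * directions[f]

    def _std(v):
        return (v - v.mean()) / v.std(ddof=0)

    z_true = 0.5 * (_std(distances) + _std(angles))
    ensemble = TrajectoryEnsemble.from_frames(
        top, frames, condition, temperature_c
    )
    truth = CoupledTrajectoryTruth(
        latent=latent,
        z_true=z_true,
        fe_cbeta_distance=distances,
        calpha_cbeta_fe_angle=angles,
        displacement_magnitude=magnitudes,
        coupled_residue_key=coupled_key,
        rho=rho,
    )
    return ensemble, truth


# ---------------------------------------------------------------------------
# Spectroscopy
# ---------------------------------------------------------------------------

def generate_spectro_dataset(
    kind: str,
    true_params: dict,
    noise_sd: float,
    design: np.ndarray,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Noisy curve of the named spectroscopic model plus its truth record.

    ``kind`` is ``"titration"`` (Morrison tight binding; params kd, damax,
    enzyme, all concentrations in μM), ``"melting"`` (Boltzmann sigmoid;
    params tm, slope in °C, lower, upper) or ``"kinetics"`` (two-summed
    exponential decay; params offset, a_fast, k_fast, a_slow, k_slow, rates
    in s⁻¹). The truth record carries the generating parameters.
    """
    from .spectro import boltzmann_curve, double_exponential_curve, morrison_curve

    design = np.asarray(design, dtype=float)
    rng = np.random.default_rng(seed)
    if kind == "titration":
        kd, damax, enzyme = (
            true_params["kd"], true_params["damax"], true_params["enzyme"]
        )
        if kd <= 0 or enzyme <= 0:
            raise ValueError("kd and enzyme concentration must be positive")
        clean = morrison_curve(design, damax, kd, enzyme)
        columns = ("substrate_concentration_um", "delta_absorbance")
    elif kind == "melting":
        tm, slope = true_params["tm"], true_params["slope"]
        lower, upper = true_params["lower"], true_params["upper"]
        if not (design.min() <= tm <= design.max()):
            raise ValueError("tm must lie inside the scanned temperature range")
        clean = boltzmann_curve(design, lower, upper, tm, slope)
        columns = ("temperature_c", "ellipticity")
    elif kind == "kinetics":
        k_fast, k_slow = true_params["k_fast"], true_params["k_slow"]
        if k_fast <= 0 or k_slow <= 0:
            raise ValueError("rate constants must be positive")
        clean = double_exponential_curve(
            design,
            true_params.get("offset", 0.0),
            true_params["a_fast"], k_fast,
            true_params["a_slow"], k_slow,
        )
        columns = ("time_s", "absorbance")
    else:
        raise ValueError(f"unknown dataset kind {kind!r}")
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    table = pd.DataFrame({columns[0]: design, columns[1]: noisy})
    truth = {"kind": kind, "noise_sd": noise_sd, **true_params}
    return table, truth
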