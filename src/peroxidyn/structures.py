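"""Structure and trajectory containers with PDB input/output.

Coordinates are carried in Å throughout; temperatures in °C. Residue numbering
follows the input file verbatim. PDB parsing and writing are delegated to
biotite; alternate-location records are resolved to the highest-occupancy
conformer (ties keep the first encountered).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import (
    EmptySelectionError,
    PDBParseError,
    ShapeMismatchError,
    TopologyIntegrityError,
)

BACKBONE_ATOM_NAMES = ("N", "CA", "C", "O")

#: Default residue names recognized as heme cofactor and palmitate substrate.
HEME_RESNAME = "HEM"
SUBSTRATE_RESNAME = "PLM"

_DIGITS = re.compile(r"\d")


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology, with its reference coordinates in Å."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    is_hetero: bool = False
    insertion_code: str = ""
    coordinates: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_id, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return _is_hydrogen(self.element, self.name)


def _is_hydrogen(element: str, name: str) -> bool:
    if element.strip():
        return element.strip().upper() in ("H", "D")
    stripped = _DIGITS.sub("", name.strip())
    return stripped[:1].upper() == "H"


class Topology:
    """Ordered atom list with a (chain, residue) index.

    Uniqueness of (chain_id, residue_id, insertion_code, atom_name) is enforced
    at construction; duplicates indicate unresolved altlocs or a corrupt file.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        seen: set[tuple] = set()
        index: dict[tuple[str, int, str], list[int]] = {}
        for i, atom in enumerate(self.atoms):
            key = (*atom.residue_key, atom.name)
            if key in seen:
                raise TopologyIntegrityError(
                    f"duplicate atom after altloc resolution: {key}"
                )
            seen.add(key)
            index.setdefault(atom.residue_key, []).append(i)
        self.residue_index: dict[tuple[str, int, str], list[int]] = index
        # cached annotation arrays for vectorized selection
        self.names = np.array([a.name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.residue_ids = np.array([a.residue_id for a in self.atoms])
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self.chain_ids = np.array([a.chain_id for a in self.atoms])
        self.hetero = np.array([a.is_hetero for a in self.atoms])
        self.hydrogen_mask = np.array([a.is_hydrogen for a in self.atoms])

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def reference_coordinates(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    def residue_keys_per_atom(self) -> list[tuple[str, int, str]]:
        return [a.residue_key for a in self.atoms]

    def signature(self) -> tuple:
        """Hashable identity used to decide whether two topologies match."""
        return tuple(
            (a.chain_id, a.residue_id, a.insertion_code, a.residue_name, a.name)
            for a in self.atoms
        )

    def find_atom(self, residue_name: str, atom_name: str) -> int:
        """Index of the first atom matching residue and atom name."""
        from .exceptions import AtomLookupError

        mask = (self.residue_names == residue_name) & (self.names == atom_name)
        hits = np.flatnonzero(mask)
        if hits.size == 0:
            raise AtomLookupError(f"no atom {atom_name!r} in residue {residue_name!r}")
        return int(hits[0])


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection resolved against a topology.

    ``include_residue_names`` adds whole residues (e.g. HEM, PLM) on top of the
    range/backbone criteria, mirroring selections such as "protein backbone
    (residues 11–412), heme, and the palmitate substrate, excluding hydrogens".
    """

    residue_range: tuple[int, int] | None = None
    backbone_only: bool = False
    include_residue_names: frozenset[str] | None = None
    exclude_hydrogens: bool = False
    atom_names: frozenset[str] | None = None

    def __post_init__(self):
        if not any(
            (
                self.residue_range is not None,
                self.backbone_only,
                self.include_residue_names is not None,
                self.exclude_hydrogens,
                self.atom_names is not None,
            )
        ):
            raise ValueError("SelectionSpec needs at least one criterion")
        if self.residue_range is not None and self.residue_range[0] > self.residue_range[1]:
            raise ValueError(f"empty residue range {self.residue_range}")


#: Fit selection used for ensemble alignment: protein backbone heavy atoms.
BACKBONE_HEAVY = SelectionSpec(
    backbone_only=True, exclude_hydrogens=True
)

#: All heavy atoms (the PCA analysis selection).
HEAVY_ATOMS = SelectionSpec(exclude_hydrogens=True)


def select_atoms(topology: Topology, spec: SelectionSpec) -> np.ndarray:
    """Resolve a :class:`SelectionSpec` to an ordered atom index array.

    Order follows the topology; the result is deterministic and idempotent.
    Raises :class:`EmptySelectionError` rather than returning an empty list.
    """
    n = topology.n_atoms
    range_or_backbone = (
        spec.residue_range is not None
        or spec.backbone_only
        or spec.atom_names is not None
    )
    if range_or_backbone:
        primary = np.ones(n, dtype=bool)
        if spec.residue_range is not None:
            lo, hi = spec.residue_range
            primary &= (topology.residue_ids >= lo) & (topology.residue_ids <= hi)
        if spec.backbone_only:
            primary &= np.isin(topology.names, BACKBONE_ATOM_NAMES)
            primary &= ~topology.hetero
        if spec.atom_names is not None:
            primary &= np.isin(topology.names, sorted(spec.atom_names))
    elif spec.include_residue_names is not None:
        primary = np.zeros(n, dtype=bool)
    else:  # only exclude_hydrogens set: start from everything
        primary = np.ones(n, dtype=bool)

    mask = primary
    if spec.include_residue_names is not None:
        mask = mask | np.isin(topology.residue_names, sorted(spec.include_residue_names))
    if spec.exclude_hydrogens:
        mask = mask & ~topology.hydrogen_mask

    indices = np.flatnonzero(mask)
    if indices.size == 0:
        raise EmptySelectionError(f"selection {spec} matched no atoms")
    return indices


@dataclass
class TrajectoryEnsemble:
    """Frames × atoms × 3 coordinates with per-frame condition and replicate tags."""

    topology: Topology
    frames: np.ndarray  # (F, N, 3), Å
    condition_labels: np.ndarray  # (F,) str
    replicate_ids: np.ndarray  # (F,) int
    temperatures: dict[str, float] = field(default_factory=dict)  # label -> °C

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ShapeMismatchError(f"frames must be (F, N, 3), got {self.frames.shape}")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ShapeMismatchError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )
        if self.frames.shape[0] < 1:
            raise ShapeMismatchError("an ensemble needs at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in trajectory frames")
        self.condition_labels = np.asarray(self.condition_labels, dtype=object)
        self.replicate_ids = np.asarray(self.replicate_ids, dtype=int)
        for arr, what in ((self.condition_labels, "condition_labels"),
                          (self.replicate_ids, "replicate_ids")):
            if arr.shape[0] != self.frames.shape[0]:
                raise ShapeMismatchError(f"{what} length != number of frames")

    @classmethod
    def from_frames(
        cls,
        topology: Topology,
        frames: np.ndarray,
        condition: str = "default",
        temperature_c: float | None = None,
        replicate_ids: np.ndarray | None = None,
    ) -> "TrajectoryEnsemble":
        frames = np.asarray(frames, dtype=float)
        f = frames.shape[0]
        labels = np.array([condition] * f, dtype=object)
        if replicate_ids is None:
            replicate_ids = np.zeros(f, dtype=int)
        temps = {} if temperature_c is None else {condition: temperature_c}
        return cls(topology, frames, labels, np.asarray(replicate_ids), temps)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.condition_labels:
            seen.setdefault(label)
        return list(seen)

    def for_condition(self, label: str) -> "TrajectoryEnsemble":
        mask = self.condition_labels == label
        if not mask.any():
            raise KeyError(f"no frames with condition {label!r}")
        return TrajectoryEnsemble(
            self.topology,
            self.frames[mask],
            self.condition_labels[mask],
            self.replicate_ids[mask],
            dict(self.temperatures),
        )

    def with_frames(self, frames: np.ndarray) -> "TrajectoryEnsemble":
        return TrajectoryEnsemble(
            self.topology,
            frames,
            self.condition_labels.copy(),
            self.replicate_ids.copy(),
            dict(self.temperatures),
        )


def concatenate_ensembles(
    ensembles: Sequence[TrajectoryEnsemble],
) -> TrajectoryEnsemble:
    """Concatenate ensembles sharing a topology, preserving frame order and tags."""
    if not ensembles:
        raise ValueError("nothing to concatenate")
    first = ensembles[0]
    sig = first.topology.signature()
    for e in ensembles[1:]:
        if e.topology.n_atoms != first.topology.n_atoms or e.topology.signature() != sig:
            raise TopologyIntegrityError(
                f"topology mismatch: {e.topology.n_atoms} atoms vs "
                f"{first.topology.n_atoms} atoms"
            )
    temps: dict[str, float] = {}
    for e in ensembles:
        temps.update(e.temperatures)
    return TrajectoryEnsemble(
        first.topology,
        np.concatenate([e.frames for e in ensembles], axis=0),
        np.concatenate([e.condition_labels for e in ensembles]),
        np.concatenate([e.replicate_ids for e in ensembles]),
        temps,
    )


# ---------------------------------------------------------------------------
# PDB input/output (via biotite)
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> None:
    """Fail early with a line number on malformed coordinate fields."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    text = line[lo:hi].strip()
                    try:
                        float(text)
                    except ValueError:
                        raise PDBParseError(
                            f"{path}, line {lineno}: malformed coordinate "
                            f"field {text!r}"
                        ) from None


def _atoms_from_atom_array(array) -> list[AtomRecord]:
    serials = getattr(array, "atom_id", None)
    ins = array.ins_code if "ins_code" in array.get_annotation_categories() else [""] * array.array_length()
    records = []
    for i in range(array.array_length()):
        records.append(
            AtomRecord(
                serial=int(serials[i]) if serials is not None else i + 1,
                name=str(array.atom_name[i]),
                element=str(array.element[i]),
                residue_name=str(array.res_name[i]),
                residue_id=int(array.res_id[i]),
                chain_id=str(array.chain_id[i]),
                is_hetero=bool(array.hetero[i]),
                insertion_code=str(ins[i]).strip(),
                coordinates=tuple(float(x) for x in array.coord[i]),
            )
        )
    return records


def _read_pdb_stack(path: Path):
    from biotite.structure.io.pdb import PDBFile

    _prescan_pdb(path)
    try:
        pdb = PDBFile.read(str(path))
        try:
            stack = pdb.get_structure(
                model=None, altloc="occupancy", extra_fields=["atom_id"]
            )
        except Exception:
            stack = pdb.get_structure(
                model=None, altloc="first", extra_fields=["atom_id"]
            )
    except PDBParseError:
        raise
    except Exception as exc:  # pragma: no cover - defensive wrap
        raise PDBParseError(f"{path}: {exc}") from exc
    return stack


def read_structure(path: str | Path) -> tuple[Topology, np.ndarray]:
    """Read a PDB file into a :class:`Topology` and its first frame (N×3, Å)."""
    stack = _read_pdb_stack(Path(path))
    first = stack[0] if stack.coord.ndim == 3 else stack
    topology = Topology(_atoms_from_atom_array(first))
    coords = np.asarray(first.coord, dtype=float)
    return topology, coords


def write_structure(
    topology: Topology, frames: np.ndarray, path: str | Path
) -> None:
    """Write one frame (N×3) or many (F×N×3) as a (multi-model) PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if not np.all(np.isfinite(frames)):
        raise ValueError("refusing to write non-finite coordinates")
    if frames.shape[1] != topology.n_atoms:
        raise ShapeMismatchError(
            f"frame atom count {frames.shape[1]} != topology {topology.n_atoms}"
        )
    n = topology.n_atoms
    array = struc.AtomArray(n)
    array.coord = frames[0]
    array.chain_id = topology.chain_ids
    array.res_id = topology.residue_ids
    array.res_name = topology.residue_names
    array.atom_name = topology.names
    array.element = topology.elements
    array.hetero = topology.hetero
    array.set_annotation(
        "ins_code", np.array([a.insertion_code for a in topology.atoms], dtype="U1")
    )
    array.set_annotation(
        "atom_id", np.array([a.serial for a in topology.atoms], dtype=int)
    )
    if frames.shape[0] == 1:
        structure = array
    else:
        structure = struc.stack([array] * frames.shape[0])
        structure.coord = frames
    pdb = PDBFile()
    pdb.set_structure(structure)
    pdb.write(str(path))


def read_trajectory(
    topology: Topology,
    paths: str | Path | Sequence[str | Path],
    fmt: str = "pdb",
    condition: str = "default",
    temperature_c: float | None = None,
) -> TrajectoryEnsemble:
    """Read trajectory frames against an existing topology.

    Each input file becomes one replicate (replicate ids follow input order).
    ``fmt`` is ``"pdb"`` (multi-model text, the portable baseline) or
    ``"xtc"``/``"dcd"`` which require the optional mdtraj dependency.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    all_frames: list[np.ndarray] = []
    rep_ids: list[np.ndarray] = []
    for rep, path in enumerate(paths):
        path = Path(path)
        if fmt == "pdb":
            stack = _read_pdb_stack(path)
            coords = np.asarray(stack.coord, dtype=float)
            if coords.ndim == 2:
                coords = coords[None]
        elif fmt in ("xtc", "dcd"):
            coords = _read_binary_trajectory(topology, path)
        else:
            raise ValueError(f"unsupported trajectory format {fmt!r}")
        if coords.shape[1] != topology.n_atoms:
            raise ShapeMismatchError(
                f"{path}: {coords.shape[1]} atoms per frame but topology "
                f"has {topology.n_atoms}"
            )
        all_frames.append(coords)
        rep_ids.append(np.full(coords.shape[0], rep, dtype=int))
    frames = np.concatenate(all_frames, axis=0)
    labels = np.array([condition] * frames.shape[0], dtype=object)
    temps = {} if temperature_c is None else {condition: temperature_c}
    return TrajectoryEnsemble(
        topology, frames, labels, np.concatenate(rep_ids), temps
    )


def _read_binary_trajectory(topology: Topology, path: Path) -> np.ndarray:
    import tempfile

    import mdtraj

    with tempfile.NamedTemporaryFile(suffix=".pdb", delete=False) as tmp:
        write_structure(topology, topology.reference_coordinates, tmp.name)
        traj = mdtraj.load(str(path), top=tmp.name)
    return np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> Å
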