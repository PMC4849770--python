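"""Domain types and file IO for conformational-ensemble analysis.

The central containers are :class:`Topology` (atoms, chain roles, charged
sidechain groups), :class:`Ensemble` (a stack of coordinate frames bound to a
topology) and :class:`Selection` (an ordered atom-index subset).  Structures
are read from fixed-column multi-model PDB files; binary trajectory formats
are routed through MDAnalysis.  Labeled matrices and per-residue profiles are
serialized as CSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "ChargedGroup",
    "Topology",
    "Ensemble",
    "Selection",
    "CHARGED_GROUP_CATALOG",
    "ELEMENT_MASSES",
    "ChainRole",
    "read_structure",
    "read_trajectory",
    "write_pdb",
    "write_matrix",
    "read_matrix",
    "select_atoms",
    "select_backbone",
    "select_all",
    "select_chains",
    "BACKBONE_ATOM_NAMES",
]

#: IUPAC 2021 standard atomic weights (amu), conventional values.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "NA": 22.990, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "CL": 35.45, "FE": 55.845, "ZN": 65.38, "MN": 54.938,
    "CU": 63.546, "F": 18.998, "BR": 79.904, "I": 126.904,
}

#: Sidechain charged groups used for salt-bridge detection.  Acidic groups
#: list carboxylate oxygens, basic groups list sidechain nitrogens.
#: Histidine and chain-terminal amino/carboxylate groups are deliberately
#: excluded from the default catalog; pass a custom catalog to include them.
CHARGED_GROUP_CATALOG: dict[str, tuple[str, tuple[str, ...]]] = {
    "ASP": ("acidic", ("OD1", "OD2")),
    "GLU": ("acidic", ("OE1", "OE2")),
    "LYS": ("basic", ("NZ",)),
    "ARG": ("basic", ("NE", "NH1", "NH2")),
}

BACKBONE_ATOM_NAMES: tuple[str, ...] = ("N", "CA", "C", "O")

#: Recognized chain roles.  "presenter" is the antigen-presenting molecule
#: (e.g. an MHC/HLA heavy chain), "peptide" the presented antigen, and the
#: receptor_* roles the recognition receptor chains (e.g. TCR alpha/beta).
ChainRole = str
CHAIN_ROLES = ("presenter", "peptide", "receptor_alpha", "receptor_beta", "other")
#: Roles grouped by side of the recognition interface.
RECEPTOR_SIDE = frozenset({"receptor_alpha", "receptor_beta"})
PRESENTER_SIDE = frozenset({"presenter", "peptide"})


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed under the fixed-column standard."""


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology.

    ``residue_id`` preserves the author numbering of the source file so that
    reports can use the same residue labels as the structural literature.
    """

    serial: int
    atom_name: str
    residue_name: str
    residue_id: int
    chain_id: str
    element: str
    mass: float
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.atom_name} has non-positive mass {self.mass}")


@dataclasses.dataclass(frozen=True)
class ChargedGroup:
    """A charged sidechain group: the salt-bridge-capable O or N atoms of one residue."""

    chain_id: str
    residue_id: int
    residue_name: str
    polarity: str  # "acidic" | "basic"
    atom_names: tuple[str, ...]
    atom_indices: tuple[int, ...]

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_id)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.residue_name}{self.residue_id}"


class Topology:
    """Ordered atom list plus chain roles and the charged-group catalog instance.

    Parameters
    ----------
    atoms:
        Atom records in file order.
    chain_roles:
        Mapping ``chain_id -> role``; missing chains default to ``"other"``.
    catalog:
        Residue-name -> (polarity, member atom names) table used to build the
        charged-group list.  Defaults to :data:`CHARGED_GROUP_CATALOG`.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        chain_roles: Mapping[str, str] | None = None,
        catalog: Mapping[str, tuple[str, tuple[str, ...]]] | None = None,
    ) -> None:
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_id, a.atom_name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in topology")
            seen.add(key)
        roles = dict(chain_roles or {})
        for role in roles.values():
            if role not in CHAIN_ROLES:
                raise ValueError(f"unknown chain role {role!r}; expected one of {CHAIN_ROLES}")
        self.chain_roles: dict[str, str] = {
            cid: roles.get(cid, "other") for cid in self.chain_ids()
        }
        self._catalog = dict(catalog if catalog is not None else CHARGED_GROUP_CATALOG)
        self.charged_groups: tuple[ChargedGroup, ...] = self._build_charged_groups()
        self.masses: np.ndarray = np.array([a.mass for a in self.atoms])

    def __len__(self) -> int:
        return len(self.atoms)

    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self) -> list[tuple[str, int, str]]:
        """(chain_id, residue_id, residue_name) in order of first appearance."""
        out: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_id)
            if key not in seen:
                seen.add(key)
                out.append((a.chain_id, a.residue_id, a.residue_name))
        return out

    def residue_atom_indices(self) -> dict[tuple[str, int], list[int]]:
        out: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault((a.chain_id, a.residue_id), []).append(i)
        return out

    def _build_charged_groups(self) -> tuple[ChargedGroup, ...]:
        by_res: dict[tuple[str, int], dict[str, int]] = {}
        names: dict[tuple[str, int], str] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_id)
            by_res.setdefault(key, {})[a.atom_name] = i
            names[key] = a.residue_name
        groups: list[ChargedGroup] = []
        for key, atom_map in by_res.items():
            resname = names[key]
            if resname not in self._catalog:
                continue
            polarity, member_names = self._catalog[resname]
            present = tuple(n for n in member_names if n in atom_map)
            if not present:
                continue
            groups.append(
                ChargedGroup(
                    chain_id=key[0],
                    residue_id=key[1],
                    residue_name=resname,
                    polarity=polarity,
                    atom_names=present,
                    atom_indices=tuple(atom_map[n] for n in present),
                )
            )
        groups.sort(key=lambda g: (g.chain_id, g.residue_id))
        return tuple(groups)

    def role_of(self, chain_id: str) -> str:
        return self.chain_roles.get(chain_id, "other")


@dataclasses.dataclass
class Ensemble:
    """T frames of N-atom coordinates (Å) bound to a topology.

    ``frame_interval`` is the sampling period between consecutive frames in
    picoseconds; it sets the time axis of drift regressions and time traces.
    """

    topology: Topology
    coordinates: np.ndarray  # (T, N, 3), Å
    frame_interval: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(f"coordinates must be (T, N, 3), got {self.coordinates.shape}")
        if self.coordinates.shape[1] != len(self.topology):
            raise ValueError(
                f"coordinate atom count {self.coordinates.shape[1]} does not match "
                f"topology atom count {len(self.topology)}"
            )
        if self.coordinates.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("ensemble coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclasses.dataclass(frozen=True)
class Selection:
    """Ordered subset of atom positions with a human-readable descriptor."""

    indices: tuple[int, ...]
    descriptor: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and (np.any(np.diff(idx) <= 0) or idx[0] < 0):
            raise ValueError("selection indices must be strictly increasing and non-negative")
        object.__setattr__(self, "indices", tuple(int(i) for i in idx))

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


def select_atoms(topology: Topology, predicate, descriptor: str = "") -> Selection:
    """Build a Selection from a per-atom predicate ``f(index, AtomRecord) -> bool``."""
    idx = tuple(i for i, a in enumerate(topology.atoms) if predicate(i, a))
    return Selection(idx, descriptor)


def select_all(topology: Topology) -> Selection:
    return Selection(tuple(range(len(topology))), "all atoms")


def select_backbone(topology: Topology, names: Iterable[str] = BACKBONE_ATOM_NAMES) -> Selection:
    names = set(names)
    return select_atoms(topology, lambda i, a: a.atom_name in names, "backbone")


def select_chains(topology: Topology, chain_ids: Iterable[str]) -> Selection:
    wanted = set(chain_ids)
    return select_atoms(
        topology, lambda i, a: a.chain_id in wanted, f"chains {','.join(sorted(wanted))}"
    )


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _element_from_columns(line: str, atom_name: str) -> str:
    elem = line[76:78].strip().upper() if len(line) >= 78 else ""
    if elem:
        return elem
    # Infer from the atom name: strip digits, take the leading alphabetic part.
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element for atom name {atom_name!r}")
    if stripped[:2].upper() in ELEMENT_MASSES and len(stripped) > 1 and not stripped[0].isdigit():
        # Two-letter element only when the PDB name starts in column 13
        # (4-character names); for standard protein atoms the first letter wins.
        first = stripped[0].upper()
        if first in ELEMENT_MASSES:
            return first
        return stripped[:2].upper()
    return stripped[0].upper()


def read_structure(
    path: str | Path,
    format: str = "pdb",
    *,
    include_hetatm: bool = False,
    chain_roles: Mapping[str, str] | None = None,
    catalog: Mapping[str, tuple[str, tuple[str, ...]]] | None = None,
    frame_interval: float = 1.0,
) -> Ensemble:
    """Read a (multi-model) PDB file into an Ensemble.

    Each MODEL block becomes one frame; a file without MODEL records yields a
    single-frame ensemble.  Masses are assigned from the element using
    standard atomic weights.  HETATM records are skipped unless
    ``include_hetatm`` is set; alternate locations other than ' '/'A' are
    dropped.
    """
    if format.lower() != "pdb":
        raise ValueError(f"unsupported structure format {format!r}; only 'pdb' is supported")
    path = Path(path)
    atoms: list[AtomRecord] = []
    frames: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] = []
    first_model_done = False
    in_model = False
    n_seen = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model = True
                current = []
                n_seen = 0
                continue
            if rec == "ENDMDL":
                in_model = False
                if first_model_done and len(current) != len(atoms):
                    raise PDBParseError(
                        f"{path}: model ending at line {lineno} has {len(current)} atoms, "
                        f"expected {len(atoms)}"
                    )
                frames.append(current)
                first_model_done = True
                current = []
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            is_het = rec == "HETATM"
            if is_het and not include_hetatm:
                continue
            try:
                altloc = line[16]
                atom_name = line[12:16].strip()
                resname = line[17:20].strip()
                chain_id = line[21].strip() or " "
                resid = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise PDBParseError(f"{path}: malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
            if altloc not in (" ", "A"):
                continue
            current.append((x, y, z))
            if not first_model_done:
                try:
                    serial = int(line[6:11])
                except ValueError:
                    serial = len(atoms) + 1
                element = _element_from_columns(line, atom_name)
                if element not in ELEMENT_MASSES:
                    raise PDBParseError(
                        f"{path}: unknown element {element!r} for atom {atom_name} "
                        f"{resname}{resid} (line {lineno})"
                    )
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        atom_name=atom_name,
                        residue_name=resname,
                        residue_id=resid,
                        chain_id=chain_id,
                        element=element,
                        mass=ELEMENT_MASSES[element],
                        is_hetatm=is_het,
                    )
                )
            else:
                n_seen += 1
    if current:
        # File without MODEL/ENDMDL bracketing (single-model PDB).
        if first_model_done and len(current) != len(atoms):
            raise PDBParseError(f"{path}: trailing partial model with {len(current)} atoms")
        frames.append(current)
    if not frames or not atoms:
        raise PDBParseError(f"{path}: no ATOM records found")
    topo = Topology(atoms, chain_roles=chain_roles, catalog=catalog)
    coords = np.asarray(frames, dtype=float)
    return Ensemble(topology=topo, coordinates=coords, frame_interval=frame_interval, label=path.stem)


def read_trajectory(
    topology_path: str | Path,
    traj_path: str | Path,
    *,
    chain_roles: Mapping[str, str] | None = None,
    catalog: Mapping[str, tuple[str, tuple[str, ...]]] | None = None,
    frame_interval: float | None = None,
) -> Ensemble:
    """Read a trajectory (multi-model PDB, or a binary format via MDAnalysis).

    The topology always comes from ``topology_path`` (a PDB file) so that
    chain roles, charged groups and masses are assigned consistently with
    :func:`read_structure`.  Coordinates are returned in Å.
    """
    traj_path = Path(traj_path)
    template = read_structure(topology_path, chain_roles=chain_roles, catalog=catalog)
    if traj_path.suffix.lower() in (".pdb", ".ent"):
        ens = read_structure(traj_path, chain_roles=chain_roles, catalog=catalog)
        if ens.n_atoms != len(template.topology):
            raise ValueError(
                f"trajectory has {ens.n_atoms} atoms but topology has {len(template.topology)}"
            )
        coords = ens.coordinates
    else:
        import MDAnalysis as mda

        uni = mda.Universe(str(topology_path), str(traj_path))
        if len(uni.atoms) != len(template.topology):
            raise ValueError(
                f"trajectory has {len(uni.atoms)} atoms but topology has {len(template.topology)}"
            )
        coords = np.array([uni.atoms.positions.copy() for _ in uni.trajectory], dtype=float)
    interval = frame_interval if frame_interval is not None else template.frame_interval
    return Ensemble(
        topology=template.topology,
        coordinates=coords,
        frame_interval=interval,
        label=traj_path.stem,
    )


def write_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model fixed-column PDB file."""
    path = Path(path)
    topo = ensemble.topology
    with open(path, "w") as fh:
        for t in range(ensemble.n_frames):
            fh.write(f"MODEL     {t + 1:4d}\n")
            for i, a in enumerate(topo.atoms):
                x, y, z = ensemble.coordinates[t, i]
                name = a.atom_name
                # PDB convention: 1-3 char names start in column 14.
                name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
                rec = "HETATM" if a.is_hetatm else "ATOM  "
                fh.write(
                    f"{rec}{a.serial % 100000:5d} {name_field} {a.residue_name:<3s} "
                    f"{a.chain_id}{a.residue_id:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{a.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Labeled matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix, path: str | Path) -> None:
    """Write a labeled matrix (DataFrame or object with .to_dataframe()) as CSV.

    Values are written at 6 significant digits; one header row of column
    labels and one leading column of row labels.
    """
    if hasattr(matrix, "to_dataframe"):
        df = matrix.to_dataframe()
    else:
        df = pd.DataFrame(matrix)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("matrix row/column labels must be unique")
    df.to_csv(path, float_format="%.6g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read back a labeled matrix written by :func:`write_matrix`."""
    return pd.read_csv(path, index_col=0)
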