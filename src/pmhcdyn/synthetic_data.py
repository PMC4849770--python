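"""Synthetic conformational ensembles with known ground truth.

The generator emulates the statistical structure that the downstream
analyses assume, without any physics: per-residue isotropic harmonic
fluctuations of tunable amplitude around a fixed mean structure, charged
sidechain pairs whose minimum O–N distance follows a programmable two-state
(formed/broken) schedule, and a three-chain presenter/peptide/receptor
architecture.  Every generated quantity has a closed-form expectation
(:func:`analytic_oracles`), so parameter recovery by the analysis modules
can be tested end to end.

No force field, integrator or solvent is involved: frames are independent
draws, which is exactly the regime in which RMSF, time-averaged inverse
distances and quasi-harmonic entropies have simple analytic values.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .entropy_cycle import oscillator_entropy_from_eigenvalues
from .io_model import AtomRecord, ELEMENT_MASSES, Ensemble, Topology

__all__ = [
    "BridgeSchedule",
    "SyntheticSpec",
    "SyntheticOracles",
    "toy_complex_topology",
    "generate_ensemble",
    "analytic_oracles",
]

# Sidechain templates: atom name -> (element, offset along e_out, offset along e_up).
# Geometry is schematic (bond lengths ~1.3-1.5 Å), adequate for exercising
# selection, mass and distance logic; it is not stereochemically accurate.
_SIDECHAINS: dict[str, list[tuple[str, str, float, float]]] = {
    "ALA": [("CB", "C", 1.5, 0.0)],
    "ASP": [
        ("CB", "C", 1.5, 0.0), ("CG", "C", 2.8, 0.0),
        ("OD1", "O", 4.0, 0.0), ("OD2", "O", 3.3, 1.2),
    ],
    "GLU": [
        ("CB", "C", 1.5, 0.0), ("CG", "C", 2.8, 0.0), ("CD", "C", 4.1, 0.0),
        ("OE1", "O", 5.3, 0.0), ("OE2", "O", 4.6, 1.2),
    ],
    "LYS": [
        ("CB", "C", 1.5, 0.0), ("CG", "C", 2.8, 0.0), ("CD", "C", 4.1, 0.0),
        ("CE", "C", 5.4, 0.0), ("NZ", "N", 6.6, 0.0),
    ],
    "ARG": [
        ("CB", "C", 1.5, 0.0), ("CG", "C", 2.8, 0.0), ("CD", "C", 4.1, 0.0),
        ("NE", "N", 5.3, 0.0), ("CZ", "C", 6.3, 0.0),
        ("NH1", "N", 7.4, 0.0), ("NH2", "N", 6.5, 1.3),
    ],
}

_CHARGED_CYCLE = ("ASP", "LYS", "GLU", "ARG")
_CA_SPACING = 3.8  # Å between consecutive CA atoms


@dataclasses.dataclass(frozen=True)
class BridgeSchedule:
    """Two-state distance schedule for one acidic/basic residue pair.

    The pair's minimum O–N distance is driven to ``formed_distance`` in a
    ``formed_fraction`` of frames and ``broken_distance`` otherwise, either
    as a leading block of formed frames (``pattern="block"``, realized
    fraction round(f*T)/T) or as seeded per-frame Bernoulli draws
    (``pattern="random"``).
    """

    acidic_key: tuple[str, int]  # (chain_id, residue_id)
    basic_key: tuple[str, int]
    formed_distance: float = 2.8
    broken_distance: float = 6.0
    formed_fraction: float = 1.0
    pattern: str = "block"

    def __post_init__(self) -> None:
        if not (0.0 <= self.formed_fraction <= 1.0):
            raise ValueError("formed_fraction must lie in [0, 1]")
        if self.formed_distance <= 0 or self.broken_distance <= 0:
            raise ValueError("schedule distances must be positive")
        if self.pattern not in ("block", "random"):
            raise ValueError(f"pattern must be 'block' or 'random', got {self.pattern!r}")

    def realized_fraction(self, n_frames: int) -> float:
        if self.pattern == "block":
            return round(self.formed_fraction * n_frames) / n_frames
        return self.formed_fraction


@dataclasses.dataclass
class SyntheticSpec:
    """Full description of a synthetic ensemble.

    ``amplitudes`` maps residue keys to per-coordinate fluctuation sigmas
    (Å); residues not listed fall back to ``noise_sigma``.  Random streams
    for atomic noise and for schedule switching are split, so changing one
    leaves the other unchanged at fixed seed.
    """

    topology: Topology
    mean_coordinates: np.ndarray
    n_frames: int = 100
    amplitudes: Mapping[tuple[str, int], float] = dataclasses.field(default_factory=dict)
    noise_sigma: float = 0.0
    schedules: Sequence[BridgeSchedule] = ()
    frame_interval: float = 1.0  # ps
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        self.mean_coordinates = np.asarray(self.mean_coordinates, dtype=float)
        if self.mean_coordinates.shape != (len(self.topology), 3):
            raise ValueError("mean coordinates do not match topology atom count")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0 or any(v < 0 for v in self.amplitudes.values()):
            raise ValueError("fluctuation amplitudes must be non-negative")

    def atom_sigmas(self) -> np.ndarray:
        amps = dict(self.amplitudes)
        return np.array(
            [
                amps.get((a.chain_id, a.residue_id), self.noise_sigma)
                for a in self.topology.atoms
            ]
        )


def _residue_frame(e_x: np.ndarray, e_out: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    e_x = e_x / np.linalg.norm(e_x)
    e_out = e_out - (e_out @ e_x) * e_x
    e_out = e_out / np.linalg.norm(e_out)
    return e_x, e_out, np.cross(e_x, e_out)


def _build_chain(
    atoms: list[AtomRecord],
    coords: list[np.ndarray],
    chain_id: str,
    residue_types: Sequence[str],
    origin: np.ndarray,
    e_x: np.ndarray,
    e_out: np.ndarray,
) -> None:
    e_x, e_out, e_up = _residue_frame(np.asarray(e_x, float), np.asarray(e_out, float))
    for i, resname in enumerate(residue_types):
        ca = origin + i * _CA_SPACING * e_x
        resid = i + 1
        entries = [
            ("N", "N", ca - 1.2 * e_x + 0.4 * e_up),
            ("CA", "C", ca),
            ("C", "C", ca + 1.2 * e_x + 0.4 * e_up),
            ("O", "O", ca + 1.4 * e_x + 1.5 * e_up),
        ]
        for name, elem, d_out, d_up in _SIDECHAINS[resname]:
            entries.append((name, elem, ca + d_out * e_out + d_up * e_up))
        for name, elem, pos in entries:
            atoms.append(
                AtomRecord(
                    serial=len(atoms) + 1,
                    atom_name=name,
                    residue_name=resname,
                    residue_id=resid,
                    chain_id=chain_id,
                    element=elem,
                    mass=ELEMENT_MASSES[elem],
                )
            )
            coords.append(np.asarray(pos, float))


def _charged_assignment(n_res: int, charged_fraction: float, rng: np.random.Generator) -> list[str]:
    n_charged = int(round(charged_fraction * n_res))
    picked = sorted(rng.choice(n_res, size=n_charged, replace=False)) if n_charged else []
    types = ["ALA"] * n_res
    for k, i in enumerate(picked):
        types[i] = _CHARGED_CYCLE[k % len(_CHARGED_CYCLE)]
    return types


def toy_complex_topology(
    n_residues_presenter: int = 10,
    n_residues_peptide: int = 3,
    n_residues_receptor: int = 8,
    charged_fraction: float = 0.4,
    seed: int = 0,
) -> tuple[Topology, np.ndarray]:
    """Miniature three-chain complex: presenter groove, bound peptide, receptor.

    Chain A (role ``presenter``) forms two parallel strands flanking a
    groove, chain B (``peptide``) lies in the groove, chain C
    (``receptor_alpha``) sits above it.  A seeded, deterministic subset of
    residues (``charged_fraction`` of each chain) is made Asp/Lys/Glu/Arg in
    rotation, with correctly named sidechain O/N atoms.  Returns the
    topology and the mean coordinates (n_atoms, 3) in Å.
    """
    for n in (n_residues_presenter, n_residues_peptide, n_residues_receptor):
        if n < 1:
            raise ValueError("all chain residue counts must be >= 1")
    if not (0.0 <= charged_fraction <= 1.0):
        raise ValueError("charged_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []

    n_a1 = (n_residues_presenter + 1) // 2
    types_a = _charged_assignment(n_residues_presenter, charged_fraction, rng)
    # presenter strand 1 (residues 1..n_a1) and strand 2, flanking y = 0
    _build_chain(atoms, coords, "A", types_a[:n_a1],
                 origin=np.array([0.0, -4.5, 0.0]), e_x=np.array([1.0, 0.0, 0.0]),
                 e_out=np.array([0.0, 0.6, 0.8]))
    chain_a2: list[AtomRecord] = []
    coords_a2: list[np.ndarray] = []
    _build_chain(chain_a2, coords_a2, "A", types_a[n_a1:],
                 origin=np.array([0.0, 4.5, 0.0]), e_x=np.array([1.0, 0.0, 0.0]),
                 e_out=np.array([0.0, -0.6, 0.8]))
    for a, c in zip(chain_a2, coords_a2):
        atoms.append(dataclasses.replace(a, serial=len(atoms) + 1, residue_id=a.residue_id + n_a1))
        coords.append(c)

    types_b = _charged_assignment(n_residues_peptide, charged_fraction, rng)
    _build_chain(atoms, coords, "B", types_b,
                 origin=np.array([1.9, 0.0, 3.5]), e_x=np.array([1.0, 0.0, 0.0]),
                 e_out=np.array([0.0, 0.0, 1.0]))
    types_c = _charged_assignment(n_residues_receptor, charged_fraction, rng)
    _build_chain(atoms, coords, "C", types_c,
                 origin=np.array([0.0, 0.0, 12.0]), e_x=np.array([1.0, 0.0, 0.0]),
                 e_out=np.array([0.0, 0.0, -1.0]))

    topo = Topology(
        atoms,
        chain_roles={"A": "presenter", "B": "peptide", "C": "receptor_alpha"},
    )
    return topo, np.asarray(coords)


def _group_for(topology: Topology, key: tuple[str, int], polarity: str):
    for g in topology.charged_groups:
        if g.residue_key == tuple(key) and g.polarity == polarity:
            return g
    raise ValueError(
        f"schedule references residue {key} which is not a {polarity} charged group"
    )


def _formed_mask(
    schedule: BridgeSchedule, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    if schedule.pattern == "block":
        n_formed = int(round(schedule.formed_fraction * n_frames))
        mask = np.zeros(n_frames, dtype=bool)
        mask[:n_formed] = True
        return mask
    return rng.random(n_frames) < schedule.formed_fraction


def generate_ensemble(spec: SyntheticSpec) -> Ensemble:
    """Draw a synthetic ensemble from a :class:`SyntheticSpec`.

    Each frame is the mean structure plus independent isotropic Gaussian
    displacements (per-residue sigma), after which each scheduled bridge
    rigidly translates the basic group's member atoms along the mean
    inter-group axis so the pair's closest O–N approach follows its
    schedule.  Noise-free, the scheduled distance is realized exactly;
    with noise it carries ~sqrt(2)*sigma jitter from the two endpoints.
    Identical spec + seed reproduces the ensemble bit for bit.
    """
    topo = spec.topology
    noise_rng, sched_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(2)
    ]
    sigmas = spec.atom_sigmas()
    coords = np.repeat(spec.mean_coordinates[None, :, :], spec.n_frames, axis=0)
    noisy = sigmas > 0
    if np.any(noisy):
        coords[:, noisy, :] += noise_rng.normal(
            size=(spec.n_frames, int(noisy.sum()), 3)
        ) * sigmas[noisy][None, :, None]

    for schedule in spec.schedules:
        acid = _group_for(topo, schedule.acidic_key, "acidic")
        base = _group_for(topo, schedule.basic_key, "basic")
        mean = spec.mean_coordinates
        o = mean[list(acid.atom_indices)]
        n = mean[list(base.atom_indices)]
        d = np.linalg.norm(o[:, None, :] - n[None, :, :], axis=2)
        i0, j0 = np.unravel_index(np.argmin(d), d.shape)
        d_mean = d[i0, j0]
        axis = (n[j0] - o[i0]) / d_mean
        mask = _formed_mask(schedule, spec.n_frames, sched_rng)
        target = np.where(mask, schedule.formed_distance, schedule.broken_distance)
        shift = (target - d_mean)[:, None] * axis[None, :]  # (T, 3)
        coords[:, list(base.atom_indices), :] += shift[:, None, :]

    return Ensemble(
        topology=topo,
        coordinates=coords,
        frame_interval=spec.frame_interval,
        label=spec.label,
    )


@dataclasses.dataclass
class SyntheticOracles:
    """Closed-form expectations for the quantities the analyses estimate."""

    rmsf: dict[tuple[str, int], float]  # per-residue expected RMSF (Å), sqrt(3)*sigma
    adjacency: dict[tuple[str, str], float]  # (acid label, basic label) -> 1/Å
    occupancy: dict[tuple[str, str], float]  # expected formed-contact fraction
    minus_T_dS: float | None  # kJ/mol; None when bridge schedules break the regime
    temperature: float


def analytic_oracles(
    spec: SyntheticSpec,
    temperature: float = 298.0,
    contact_cutoff: float = 3.2,
) -> SyntheticOracles:
    """Ground-truth expectations for a synthetic spec.

    Per-residue expected RMSF is sqrt(3)*sigma (isotropic Gaussian).  For a
    noise-free schedule with realized formed fraction f, the expected
    adjacency weight is f/d_formed + (1-f)/d_broken and the expected
    occupancy is the schedule fraction spent below the contact cutoff.  The
    quasi-harmonic entropy oracle applies only in the independent-oscillator
    regime (no schedules): there the covariance eigenvalues are m_i*sigma_i²,
    three per fluctuating atom, and the entropy follows in closed form.
    """
    rmsf = {
        (c, r): float(np.sqrt(3.0) * dict(spec.amplitudes).get((c, r), spec.noise_sigma))
        for c, r, _ in spec.topology.residues()
    }
    adjacency: dict[tuple[str, str], float] = {}
    occupancy: dict[tuple[str, str], float] = {}
    for s in spec.schedules:
        acid = _group_for(spec.topology, s.acidic_key, "acidic")
        base = _group_for(spec.topology, s.basic_key, "basic")
        f = s.realized_fraction(spec.n_frames)
        key = (acid.label, base.label)
        adjacency[key] = f / s.formed_distance + (1.0 - f) / s.broken_distance
        occupancy[key] = f * (s.formed_distance < contact_cutoff) + (1.0 - f) * (
            s.broken_distance < contact_cutoff
        )
    if spec.schedules:
        minus_t_ds = None
    else:
        sigmas = spec.atom_sigmas()
        masses = spec.topology.masses
        lam = np.repeat(masses[sigmas > 0] * sigmas[sigmas > 0] ** 2, 3)
        minus_t_ds = (
            oscillator_entropy_from_eigenvalues(lam, temperature=temperature)
            if len(lam)
            else 0.0
        )
    return SyntheticOracles(
        rmsf=rmsf,
        adjacency=adjacency,
        occupancy=occupancy,
        minus_T_dS=minus_t_ds,
        temperature=temperature,
    )


def analytic_entropy(spec: SyntheticSpec, temperature: float = 298.0) -> float:
    """Strict entropy oracle: raises outside the independent-oscillator regime."""
    if spec.schedules:
        raise ValueError(
            "entropy oracle requires the independent-oscillator regime "
            "(no bridge schedules in the spec)"
        )
    result = analytic_oracles(spec, temperature=temperature).minus_T_dS
    assert result is not None
    return result
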