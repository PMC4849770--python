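"""Salt-bridge networks as weighted adjacency matrices, and their comparison.

A salt bridge is an electrostatic contact between a sidechain carboxylate
oxygen of an acidic residue and a sidechain nitrogen of a basic residue.
Candidate pairs are detected with a generous distance cutoff (default 8 Å on
the per-frame minimum O–N distance); each detected pair contributes a matrix
entry

    a_ij = (1/T) * sum_t 1 / d_ij(t)        [1/Å]

the time-averaged inverse distance, proportional to the pair's average
Coulomb interaction strength.  Networks from different ensembles are
compared through the Frobenius inner product Tr(A Bᵀ) and through a
normalized Frobenius distance ||A/||A||_F − B/||B||_F||_F, a proper metric
on matrix "patterns" that ignores overall scale.  A stricter contact
criterion (default: O–N distance below 3.2 Å in at least half the frames)
counts the bridges actually formed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import (
    PRESENTER_SIDE,
    RECEPTOR_SIDE,
    ChargedGroup,
    Ensemble,
    Topology,
)

__all__ = [
    "BridgePair",
    "DistanceSeries",
    "SaltBridgeMatrix",
    "find_candidate_pairs",
    "distance_series",
    "adjacency_matrix",
    "frobenius_inner",
    "frobenius_norm",
    "frobenius_distance",
    "align_matrices",
    "intermolecular_submatrix",
    "count_bridges",
    "DEFAULT_DETECTION_CUTOFF",
    "DEFAULT_CONTACT_CUTOFF",
    "DEFAULT_NORMALIZATION",
]

DEFAULT_DETECTION_CUTOFF = 8.0  # Å, candidate-pair search
DEFAULT_CONTACT_CUTOFF = 3.2  # Å, formed-contact criterion
#: Default weight normalization: the inverse of a tight 2.8 Å contact, the
#: practical ceiling of a time-averaged inverse O–N distance (≈0.357 1/Å).
DEFAULT_NORMALIZATION = 1.0 / 2.8


@dataclasses.dataclass(frozen=True)
class BridgePair:
    """An (acidic, basic) charged-group pair that can form a salt bridge."""

    acidic: ChargedGroup
    basic: ChargedGroup
    intermolecular: bool

    @property
    def label(self) -> tuple[str, str]:
        return (self.acidic.label, self.basic.label)

    def __repr__(self) -> str:  # compact: "A:ASP4--B:LYS7"
        return f"{self.acidic.label}--{self.basic.label}"


@dataclasses.dataclass
class DistanceSeries:
    """Per-frame minimum O–N distance (Å) for one candidate pair."""

    pair: BridgePair
    values: np.ndarray

    def inverse(self) -> np.ndarray:
        return 1.0 / self.values

    def to_dataframe(self, frame_interval: float = 1.0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ps": np.arange(len(self.values)) * frame_interval,
                "distance_A": self.values,
                "inverse_distance_per_A": self.inverse(),
            }
        )


@dataclasses.dataclass
class SaltBridgeMatrix:
    """Labeled acidic × basic matrix of (possibly normalized) bridge weights."""

    row_labels: tuple[str, ...]  # acidic residues
    col_labels: tuple[str, ...]  # basic residues
    weights: np.ndarray  # (n_rows, n_cols), >= 0
    normalized: bool = False
    normalization_constant: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("weight shape does not match labels")
        if self.weights.size and self.weights.min() < 0:
            raise ValueError("bridge weights must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.row_labels), columns=list(self.col_labels))

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, normalized: bool = False, normalization_constant: float = 1.0
    ) -> "SaltBridgeMatrix":
        return cls(
            row_labels=tuple(str(i) for i in df.index),
            col_labels=tuple(str(c) for c in df.columns),
            weights=df.to_numpy(dtype=float),
            normalized=normalized,
            normalization_constant=normalization_constant,
        )


def _pair_min_distances(ensemble: Ensemble, acidic: ChargedGroup, basic: ChargedGroup) -> np.ndarray:
    """Per-frame minimum distance over all acidic-O × basic-N member combinations."""
    o = ensemble.coordinates[:, list(acidic.atom_indices), :]  # (T, nO, 3)
    n = ensemble.coordinates[:, list(basic.atom_indices), :]  # (T, nN, 3)
    d = np.linalg.norm(o[:, :, None, :] - n[:, None, :, :], axis=3)  # (T, nO, nN)
    return d.min(axis=(1, 2))


def _is_intermolecular(topology: Topology, acidic: ChargedGroup, basic: ChargedGroup) -> bool:
    ra, rb = topology.role_of(acidic.chain_id), topology.role_of(basic.chain_id)
    return (ra in PRESENTER_SIDE and rb in RECEPTOR_SIDE) or (
        ra in RECEPTOR_SIDE and rb in PRESENTER_SIDE
    )


def find_candidate_pairs(
    ensemble: Ensemble, cutoff: float = DEFAULT_DETECTION_CUTOFF
) -> list[BridgePair]:
    """All acidic/basic group pairs whose minimum O–N distance ever reaches the cutoff.

    A pair qualifies if in at least one frame the minimum distance over its
    member-atom combinations is <= ``cutoff``.  Pairs are returned sorted by
    (chain, residue_id) of the acidic then the basic residue.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    topo = ensemble.topology
    acidics = [g for g in topo.charged_groups if g.polarity == "acidic"]
    basics = [g for g in topo.charged_groups if g.polarity == "basic"]
    pairs: list[BridgePair] = []
    for ag in acidics:
        for bg in basics:
            if ag.residue_key == bg.residue_key:
                continue
            dmin = _pair_min_distances(ensemble, ag, bg)
            if dmin.min() <= cutoff:
                pairs.append(
                    BridgePair(acidic=ag, basic=bg, intermolecular=_is_intermolecular(topo, ag, bg))
                )
    pairs.sort(key=lambda p: (p.acidic.residue_key, p.basic.residue_key))
    return pairs


def distance_series(ensemble: Ensemble, pair: BridgePair) -> DistanceSeries:
    """Per-frame minimum O–N distance time series for one pair."""
    n_atoms = ensemble.n_atoms
    for grp in (pair.acidic, pair.basic):
        bad = [n for n, i in zip(grp.atom_names, grp.atom_indices) if i >= n_atoms]
        if bad:
            raise ValueError(f"pair {pair!r}: member atoms {bad} are not in the ensemble")
    return DistanceSeries(pair=pair, values=_pair_min_distances(ensemble, pair.acidic, pair.basic))


def adjacency_matrix(
    ensemble: Ensemble,
    pairs: Sequence[BridgePair],
    normalize: bool = False,
    normalization_constant: float = DEFAULT_NORMALIZATION,
) -> SaltBridgeMatrix:
    """Weighted adjacency matrix of time-averaged inverse bridge distances.

    Entry (i, j) is mean_t 1/d_ij(t) for a detected pair, 0 otherwise.  With
    ``normalize`` the weights are divided by ``normalization_constant``
    (default: the inverse of a tight 2.8 Å contact), mapping a permanent
    close contact to ≈1.
    """
    acid_labels = sorted(
        {p.acidic.label for p in pairs},
        key=lambda s: _label_sort_key(pairs, s, "acidic"),
    )
    base_labels = sorted(
        {p.basic.label for p in pairs},
        key=lambda s: _label_sort_key(pairs, s, "basic"),
    )
    w = np.zeros((len(acid_labels), len(base_labels)))
    for p in pairs:
        d = _pair_min_distances(ensemble, p.acidic, p.basic)
        if np.any(d <= 0):
            raise ValueError(f"pair {p!r} has a non-positive distance in some frame")
        w[acid_labels.index(p.acidic.label), base_labels.index(p.basic.label)] = np.mean(1.0 / d)
    if normalize:
        w = w / normalization_constant
    return SaltBridgeMatrix(
        row_labels=tuple(acid_labels),
        col_labels=tuple(base_labels),
        weights=w,
        normalized=normalize,
        normalization_constant=normalization_constant if normalize else 1.0,
    )


def _label_sort_key(pairs: Sequence[BridgePair], label: str, side: str):
    for p in pairs:
        grp = p.acidic if side == "acidic" else p.basic
        if grp.label == label:
            return grp.residue_key
    return (label, 0)


def _check_aligned(a: SaltBridgeMatrix, b: SaltBridgeMatrix) -> None:
    if a.row_labels != b.row_labels or a.col_labels != b.col_labels:
        raise ValueError(
            "matrices have different label sets; run align_matrices first"
        )


def frobenius_inner(a: SaltBridgeMatrix, b: SaltBridgeMatrix) -> float:
    """Frobenius inner product Tr(A Bᵀ) = sum_ij a_ij b_ij of two aligned matrices."""
    _check_aligned(a, b)
    return float(np.sum(a.weights * b.weights))


def frobenius_norm(a: SaltBridgeMatrix) -> float:
    return float(np.linalg.norm(a.weights))


def frobenius_distance(
    a: SaltBridgeMatrix, b: SaltBridgeMatrix, normalized: bool = True
) -> float:
    """Frobenius distance between two aligned salt-bridge matrices.

    With ``normalized`` (the default) each matrix is first divided by its own
    Frobenius norm, so the distance compares bridge *patterns* irrespective
    of overall interaction strength; it is 0 for any matrix against itself
    and at most sqrt(2) for matrices of disjoint support.  A zero matrix is
    left as zero (and two zero matrices are at distance 0).
    """
    _check_aligned(a, b)
    wa, wb = a.weights, b.weights
    if normalized:
        na, nb = np.linalg.norm(wa), np.linalg.norm(wb)
        wa = wa / na if na > 0 else wa
        wb = wb / nb if nb > 0 else wb
    return float(np.linalg.norm(wa - wb))


def align_matrices(
    a: SaltBridgeMatrix, b: SaltBridgeMatrix
) -> tuple[SaltBridgeMatrix, SaltBridgeMatrix]:
    """Re-index two matrices on the union of their row and column labels.

    Entries absent from a matrix become 0.  Label order: labels of ``a``
    first (in their original order), then new labels of ``b`` in order.
    """
    rows = list(a.row_labels) + [r for r in b.row_labels if r not in a.row_labels]
    cols = list(a.col_labels) + [c for c in b.col_labels if c not in a.col_labels]

    def expand(m: SaltBridgeMatrix) -> SaltBridgeMatrix:
        df = m.to_dataframe().reindex(index=rows, columns=cols, fill_value=0.0)
        return SaltBridgeMatrix(
            row_labels=tuple(rows),
            col_labels=tuple(cols),
            weights=df.to_numpy(dtype=float),
            normalized=m.normalized,
            normalization_constant=m.normalization_constant,
        )

    return expand(a), expand(b)


def intermolecular_submatrix(m: SaltBridgeMatrix, topology: Topology) -> SaltBridgeMatrix:
    """Zero out entries that do not span the presenter/peptide–receptor interface.

    Labels are resolved back to chains via their "chain:RESid" form; an entry
    survives only if one residue sits on the presenter/peptide side and the
    other on the receptor side.
    """
    role_by_chain = topology.chain_roles

    def side(label: str) -> str:
        chain = label.split(":", 1)[0]
        if chain not in role_by_chain:
            raise ValueError(f"label {label!r} refers to unknown chain {chain!r}")
        role = role_by_chain[chain]
        if role in RECEPTOR_SIDE:
            return "receptor"
        if role in PRESENTER_SIDE:
            return "presenter"
        return "other"

    w = m.weights.copy()
    for i, r in enumerate(m.row_labels):
        for j, c in enumerate(m.col_labels):
            sides = {side(r), side(c)}
            if sides != {"presenter", "receptor"}:
                w[i, j] = 0.0
    return SaltBridgeMatrix(
        row_labels=m.row_labels,
        col_labels=m.col_labels,
        weights=w,
        normalized=m.normalized,
        normalization_constant=m.normalization_constant,
    )


def count_bridges(
    ensemble: Ensemble,
    pairs: Sequence[BridgePair],
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    occupancy: float = 0.5,
) -> tuple[int, dict[tuple[str, str], float]]:
    """Count formed salt bridges by contact occupancy.

    A pair counts as a formed bridge if the fraction of frames with minimum
    O–N distance strictly below ``contact_cutoff`` is at least ``occupancy``.
    Returns the count and the per-pair occupancies.
    """
    if not (0 < occupancy <= 1):
        raise ValueError("occupancy must be in (0, 1]")
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    occupancies: dict[tuple[str, str], float] = {}
    count = 0
    for p in pairs:
        d = _pair_min_distances(ensemble, p.acidic, p.basic)
        frac = float(np.mean(d < contact_cutoff))
        occupancies[p.label] = frac
        if frac >= occupancy:
            count += 1
    return count, occupancies
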