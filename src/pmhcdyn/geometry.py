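"""Rigid-body geometry of conformational ensembles.

Centers of mass, mass-weighted radii of gyration, Kabsch superposition and
principal inertia frames.  The radius of gyration of an atom set is

    R_G = sqrt( sum_i m_i |r_i - r_CoM|^2 / sum_i m_i )

which grows when a complex dissociates or a chain unfolds, making its time
series a cheap stability monitor.  Principal frames come from the
eigendecomposition of the inertia tensor and are used to express the motion
of one body (e.g. a bound peptide) in the reference frame of another (the
presenting molecule), independent of global rigid motion.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_model import Ensemble, Selection

__all__ = [
    "PrincipalFrame",
    "RgSeries",
    "center_of_mass",
    "radius_of_gyration",
    "kabsch_superpose",
    "superpose_frames",
    "principal_frame",
    "project_com_trace",
]


@dataclasses.dataclass(frozen=True)
class PrincipalFrame:
    """Center of mass and principal inertia axes of an atom set.

    ``axes`` rows are unit principal axes sorted by descending inertia
    moment; the basis is right-handed (det = +1).  ``degenerate`` flags
    (near-)spherically symmetric mass distributions whose axes are not
    uniquely defined.
    """

    com: np.ndarray  # (3,) Å
    axes: np.ndarray  # (3, 3), rows = axes, descending moment
    moments: np.ndarray  # (3,) amu·Å²
    degenerate: bool = False


@dataclasses.dataclass
class RgSeries:
    """Per-frame radius of gyration (Å) with its mean and standard error."""

    values: np.ndarray
    selection: str
    mean: float
    sem: float


def _sel_arrays(ensemble: Ensemble, selection: Selection) -> tuple[np.ndarray, np.ndarray]:
    if len(selection) == 0:
        raise ValueError("selection is empty")
    idx = selection.as_array()
    return ensemble.coordinates[:, idx, :], ensemble.topology.masses[idx]


def center_of_mass(ensemble: Ensemble, selection: Selection, frame: int = 0) -> np.ndarray:
    """Mass-weighted center of an atom selection at one frame (Å)."""
    coords, masses = _sel_arrays(ensemble, selection)
    return masses @ coords[frame] / masses.sum()


def radius_of_gyration(ensemble: Ensemble, selection: Selection) -> RgSeries:
    """Per-frame mass-weighted radius of gyration of a selection."""
    coords, masses = _sel_arrays(ensemble, selection)
    total = masses.sum()
    com = np.einsum("j,tjk->tk", masses, coords) / total  # (T, 3)
    d2 = np.sum((coords - com[:, None, :]) ** 2, axis=2)  # (T, N)
    rg = np.sqrt(d2 @ masses / total)
    sem = float(rg.std(ddof=1) / np.sqrt(len(rg))) if len(rg) > 1 else 0.0
    return RgSeries(values=rg, selection=selection.descriptor, mean=float(rg.mean()), sem=sem)


def _kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (3x3) taking centered ``mobile`` onto centered ``reference``."""
    h = mobile.T @ reference
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    return u @ flip @ vt


def _check_noncollinear(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError("superposition requires at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("superposition selection is collinear or degenerate")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: Selection | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of one frame onto another.

    Fits ``mobile`` onto ``reference`` using the atoms of ``selection``
    (all atoms if None), applies the transform to the whole mobile frame and
    returns ``(transformed_coordinates, rmsd)`` where the RMSD is evaluated
    over the fit selection.  Only proper rotations are allowed.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = selection.as_array() if selection is not None else np.arange(len(mobile))
    if selection is not None and len(selection) == 0:
        raise ValueError("selection is empty")
    msel, rsel = mobile[idx], reference[idx]
    _check_noncollinear(msel)
    mc, rc = msel.mean(axis=0), rsel.mean(axis=0)
    rot = _kabsch_rotation(msel - mc, rsel - rc)
    moved = (mobile - mc) @ rot + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved[idx] - rsel) ** 2, axis=1))))
    return moved, rmsd


def superpose_frames(
    coordinates: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray,
) -> np.ndarray:
    """Vectorized Kabsch fit of every frame in a (T, N, 3) stack onto a reference.

    Fitting is unweighted over ``fit_indices``; the transform is applied to
    all atoms of each frame.  Uses a batched 3x3 SVD, so the cost is one
    einsum plus T small decompositions.
    """
    coords = np.asarray(coordinates, dtype=float)
    ref = np.asarray(reference, dtype=float)
    fsel = coords[:, fit_indices, :]
    rsel = ref[fit_indices]
    _check_noncollinear(rsel)
    mc = fsel.mean(axis=1)  # (T, 3)
    rc = rsel.mean(axis=0)  # (3,)
    h = np.einsum("tni,nj->tij", fsel - mc[:, None, :], rsel - rc)
    u, s, vt = np.linalg.svd(h)
    det = np.sign(np.linalg.det(np.einsum("tij,tjk->tik", u, vt)))
    u[:, :, 2] *= det[:, None]
    rot = np.einsum("tij,tjk->tik", u, vt)  # (T, 3, 3)
    return np.einsum("tni,tij->tnj", coords - mc[:, None, :], rot) + rc


def _inertia_tensor(coords: np.ndarray, masses: np.ndarray, com: np.ndarray) -> np.ndarray:
    d = coords - com
    r2 = np.sum(d * d, axis=1)
    return np.einsum("i,i->", masses, r2) * np.eye(3) - np.einsum("i,ij,ik->jk", masses, d, d)


def principal_frame(
    ensemble: Ensemble,
    selection: Selection,
    frame: int = 0,
    prev_axes: np.ndarray | None = None,
    anchor: np.ndarray | None = None,
) -> PrincipalFrame:
    """Principal inertia frame of a selection at one frame.

    Axis signs are intrinsically ambiguous; they are resolved by (in order of
    precedence) continuity with ``prev_axes`` (maximize the dot product with
    the previous frame's axes), a covariant ``anchor`` direction (axes flipped
    so their dot with the anchor is non-negative), or a fixed convention
    (largest-magnitude component positive).  The third axis is always rebuilt
    as the cross product of the first two, so the basis stays right-handed.
    """
    coords, masses = _sel_arrays(ensemble, selection)
    pts = coords[frame]
    com = masses @ pts / masses.sum()
    tensor = _inertia_tensor(pts, masses, com)
    moments, vecs = np.linalg.eigh(tensor)  # ascending
    order = np.argsort(moments)[::-1]
    moments = moments[order]
    axes = vecs[:, order].T  # rows = axes, descending moment
    spread = moments.max() - moments.min()
    degenerate = bool(spread < 1e-8 * max(moments.max(), 1.0))

    for k in range(2):
        if prev_axes is not None:
            if axes[k] @ prev_axes[k] < 0:
                axes[k] = -axes[k]
        elif anchor is not None:
            if axes[k] @ anchor < 0:
                axes[k] = -axes[k]
        else:
            j = int(np.argmax(np.abs(axes[k])))
            if axes[k, j] < 0:
                axes[k] = -axes[k]
    axes[2] = np.cross(axes[0], axes[1])
    return PrincipalFrame(com=com, axes=axes, moments=moments, degenerate=degenerate)


def project_com_trace(
    ensemble: Ensemble,
    body: Selection,
    probe: Selection,
) -> np.ndarray:
    """Trace of the probe's center of mass in the body's principal frame.

    Returns a (T, 3) array: per frame, the probe CoM expressed in the
    coordinate system spanned by the body's principal inertia axes, origin at
    the body CoM.  The first frame's axis signs are anchored so the probe
    offset has non-negative components; later frames resolve the sign
    ambiguity by continuity of the projected components themselves, which are
    rotation invariants — so the trace is unchanged under arbitrary global
    rigid motions applied per frame.
    """
    T = ensemble.n_frames
    trace = np.empty((T, 3))
    prev_proj: np.ndarray | None = None
    for t in range(T):
        probe_com = center_of_mass(ensemble, probe, frame=t)
        body_com = center_of_mass(ensemble, body, frame=t)
        offset = probe_com - body_com
        pf = principal_frame(ensemble, body, frame=t, anchor=offset)
        proj = pf.axes @ offset  # components all >= 0 up to handedness of axis 3
        if prev_proj is not None:
            # flip first two axes to keep each projected component continuous;
            # the third axis follows from right-handedness
            s = np.ones(3)
            for k in range(2):
                if abs(-proj[k] - prev_proj[k]) < abs(proj[k] - prev_proj[k]):
                    s[k] = -1.0
            s[2] = s[0] * s[1]
            proj = s * proj
        prev_proj = proj
        trace[t] = proj
    return trace
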