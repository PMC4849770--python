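"""Fluctuation statistics for comparing conformational ensembles.

RMSD time series with linear-drift estimates, iteratively fitted average
structures, per-residue RMSF profiles, profile difference maps and
significance tests between profiles.  All superpositions are unweighted
least-squares (Kabsch) fits over a user-chosen selection, conventionally the
main-chain atoms N, CA, C, O.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import kabsch_superpose, superpose_frames
from .io_model import BACKBONE_ATOM_NAMES, Ensemble, Selection, Topology

__all__ = [
    "RmsdSeries",
    "FluctuationProfile",
    "TTestReport",
    "rmsd_series",
    "average_structure",
    "rmsf_profile",
    "profile_difference",
    "compare_profiles_ttest",
    "residue_rmsd_map",
]

#: pm per Å — converts an OLS slope in Å/ps to pm/ns (1 Å/ps = 1e5 pm/ns).
_A_PER_PS_TO_PM_PER_NS = 1.0e5


@dataclasses.dataclass
class RmsdSeries:
    """RMSD (Å) of each frame from a reference after superposition.

    ``drift`` is the ordinary-least-squares slope of RMSD against time,
    reported in pm/ns with its standard error: a sustained positive drift
    indicates the ensemble is still relaxing away from the reference.
    """

    values: np.ndarray
    reference: str
    average: float
    maximum: float
    drift: float  # pm/ns
    drift_stderr: float  # pm/ns

    def to_dataframe(self, frame_interval: float = 1.0) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ps": np.arange(len(self.values)) * frame_interval, "rmsd_A": self.values}
        )


@dataclasses.dataclass
class FluctuationProfile:
    """Per-residue RMSF (Å) with the residue keys and atom scope that produced it."""

    residue_keys: list[tuple[str, int]]
    rmsf: np.ndarray
    scope: str  # "backbone" | "all"

    def to_dataframe(self) -> pd.DataFrame:
        chains, resids = zip(*self.residue_keys) if self.residue_keys else ((), ())
        return pd.DataFrame({"chain": chains, "residue_id": resids, "rmsf_A": self.rmsf})


@dataclasses.dataclass
class TTestReport:
    """Result of a residue-wise t-test between two fluctuation profiles."""

    statistic: float
    pvalue: float
    significant: bool
    alpha: float
    mean_difference: float
    df: float
    paired: bool
    degenerate: bool = False


def rmsd_series(
    ensemble: Ensemble,
    reference: np.ndarray,
    fit_selection: Selection,
    measure_selection: Selection | None = None,
    reference_label: str = "reference",
) -> RmsdSeries:
    """Per-frame RMSD from a reference structure.

    Each frame is Kabsch-fitted onto the reference over ``fit_selection``;
    the RMSD is then measured over ``measure_selection`` (defaults to the fit
    selection).  The drift is the OLS slope of RMSD versus time converted
    from Å/ps to pm/ns.
    """
    if measure_selection is None:
        measure_selection = fit_selection
    fitted = superpose_frames(ensemble.coordinates, reference, fit_selection.as_array())
    midx = measure_selection.as_array()
    diff = fitted[:, midx, :] - reference[midx]
    values = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
    t_ps = ensemble.times_ps()
    if len(values) > 1 and np.ptp(t_ps) > 0:
        res = stats.linregress(t_ps, values)
        drift = float(res.slope) * _A_PER_PS_TO_PM_PER_NS
        stderr = float(res.stderr) * _A_PER_PS_TO_PM_PER_NS
    else:
        drift, stderr = 0.0, 0.0
    return RmsdSeries(
        values=values,
        reference=reference_label,
        average=float(values.mean()),
        maximum=float(values.max()),
        drift=drift,
        drift_stderr=stderr,
    )


def average_structure(
    ensemble: Ensemble,
    fit_selection: Selection,
    tol: float = 1e-6,
    max_iter: int = 10,
) -> np.ndarray:
    """Iteratively fitted mean structure of an ensemble.

    Frames are superposed onto the current mean (initially the first frame)
    and re-averaged until the mean moves less than ``tol`` Å (RMS over
    atoms) between iterations.
    """
    if ensemble.n_frames < 2:
        return ensemble.coordinates[0].copy()
    ref = ensemble.coordinates[0]
    fit_idx = fit_selection.as_array()
    shift = np.inf
    for _ in range(max_iter):
        fitted = superpose_frames(ensemble.coordinates, ref, fit_idx)
        mean = fitted.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((mean - ref) ** 2, axis=1))))
        ref = mean
        if shift < tol:
            return ref
    raise RuntimeError(
        f"average structure did not converge in {max_iter} iterations (last shift {shift:.2e} Å)"
    )


def _residue_scope_indices(
    topology: Topology, scope: str
) -> list[tuple[tuple[str, int], np.ndarray]]:
    if scope not in ("backbone", "all"):
        raise ValueError(f"scope must be 'backbone' or 'all', got {scope!r}")
    out: list[tuple[tuple[str, int], np.ndarray]] = []
    for key, idx in topology.residue_atom_indices().items():
        if scope == "backbone":
            idx = [i for i in idx if topology.atoms[i].atom_name in BACKBONE_ATOM_NAMES]
        if idx:
            out.append((key, np.asarray(idx, dtype=int)))
    return out


def rmsf_profile(
    ensemble: Ensemble,
    fit_selection: Selection,
    scope: str = "backbone",
) -> FluctuationProfile:
    """Per-residue root-mean-square fluctuation about the fitted mean structure.

    Per atom, RMSF_i = sqrt(<|r_i - <r_i>|^2>) after superposing every frame
    onto the iteratively fitted average structure.  Residue values are the
    mass-weighted mean of the residue's atoms within ``scope``.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    avg = average_structure(ensemble, fit_selection)
    fitted = superpose_frames(ensemble.coordinates, avg, fit_selection.as_array())
    mean = fitted.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
    masses = ensemble.topology.masses
    keys: list[tuple[str, int]] = []
    vals: list[float] = []
    for key, idx in _residue_scope_indices(ensemble.topology, scope):
        w = masses[idx]
        keys.append(key)
        vals.append(float(per_atom[idx] @ w / w.sum()))
    return FluctuationProfile(residue_keys=keys, rmsf=np.asarray(vals), scope=scope)


def profile_difference(a: FluctuationProfile, b: FluctuationProfile) -> pd.DataFrame:
    """Elementwise a − b per residue; positive where a fluctuates more."""
    if a.residue_keys != b.residue_keys:
        missing = set(a.residue_keys) ^ set(b.residue_keys)
        raise ValueError(f"profiles cover different residues: {sorted(missing)}")
    chains, resids = zip(*a.residue_keys)
    return pd.DataFrame(
        {"chain": chains, "residue_id": resids, "delta_rmsf_A": a.rmsf - b.rmsf}
    )


def compare_profiles_ttest(
    a: FluctuationProfile,
    b: FluctuationProfile,
    alpha: float = 0.05,
    paired: bool = True,
) -> TTestReport:
    """Two-sided t-test of whether two RMSF profiles differ on average.

    The default pairs residues (each residue contributes one difference);
    ``paired=False`` runs Welch's unequal-variance test instead.  A
    zero-variance difference vector yields a NaN p value flagged degenerate.
    """
    if a.residue_keys != b.residue_keys:
        raise ValueError("profiles cover different residues")
    if len(a.rmsf) < 3:
        raise ValueError("t-test requires at least 3 residues")
    diff = a.rmsf - b.rmsf
    if paired:
        df = float(len(diff) - 1)
        if np.allclose(diff.std(ddof=1), 0.0):
            return TTestReport(
                statistic=float("nan"), pvalue=float("nan"), significant=False,
                alpha=alpha, mean_difference=float(diff.mean()), df=df,
                paired=True, degenerate=True,
            )
        res = stats.ttest_rel(a.rmsf, b.rmsf)
        df_out = df
    else:
        if np.allclose(a.rmsf.std(ddof=1), 0.0) and np.allclose(b.rmsf.std(ddof=1), 0.0):
            return TTestReport(
                statistic=float("nan"), pvalue=float("nan"), significant=False,
                alpha=alpha, mean_difference=float(diff.mean()),
                df=float(2 * len(diff) - 2), paired=False, degenerate=True,
            )
        res = stats.ttest_ind(a.rmsf, b.rmsf, equal_var=False)
        df_out = float(res.df)
    pvalue = float(res.pvalue)
    return TTestReport(
        statistic=float(res.statistic),
        pvalue=pvalue,
        significant=bool(pvalue < alpha),
        alpha=alpha,
        mean_difference=float(diff.mean()),
        df=df_out,
        paired=paired,
    )


def residue_rmsd_map(
    avg_a: np.ndarray,
    avg_b: np.ndarray,
    topology: Topology,
    fit_selection: Selection,
    scope: str = "backbone",
) -> pd.DataFrame:
    """Per-residue RMSD between two structures after one global superposition.

    ``avg_b`` is fitted onto ``avg_a`` over ``fit_selection``; the map then
    reports, residue by residue, the RMSD over that residue's ``scope``
    atoms.  Used to localize where two average structures differ.
    """
    if avg_a.shape != avg_b.shape:
        raise ValueError("structures have different shapes")
    moved, _ = kabsch_superpose(avg_b, avg_a, fit_selection)
    rows = []
    for key, idx in _residue_scope_indices(topology, scope):
        d = moved[idx] - avg_a[idx]
        rows.append((key[0], key[1], float(np.sqrt(np.mean(np.sum(d * d, axis=1))))))
    return pd.DataFrame(rows, columns=["chain", "residue_id", "rmsd_A"])
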