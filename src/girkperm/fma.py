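"""Functional mode analysis (FMA).

FMA finds the collective motion of a structural ensemble that is maximally
correlated with a scalar functional quantity f(t): the configuration-space
coordinates are reduced to a principal-component basis (50 components by
default), f(t) is regressed linearly onto the component projections over a
build window, and the model is cross-validated on a disjoint window with
Pearson's R and mutual information.

On an orthonormal PCA basis the least-squares regression is exactly the
maximally-correlated-motion formulation, so ordinary least squares is used
rather than an iterative partial-least-squares scheme.  Two collective
displacement vectors are exposed:

* the maximally correlated motion (MCM), Σ_k β_k v_k normalised — the
  direction along which motion best predicts f, and
* the ensemble-weighted MCM (ewMCM), Σ_k β_k λ_k v_k normalised — the
  eigenvalue- (amplitude-) weighted combination, which emphasises how much
  each component actually moves in the ensemble and is the vector used for
  visualisation and per-atom correlation weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from girkperm.errors import DataError
from girkperm.trajectory import AtomSelection, Trajectory

__all__ = [
    "PCABasis",
    "FunctionalMode",
    "pca_backbone",
    "fma_build",
    "fma_cross_validate",
    "mutual_information",
    "project_mode_on_structure",
    "time_range_to_frames",
]


@dataclass
class PCABasis:
    """Orthonormal configuration-space basis from backbone PCA."""

    mean_structure: np.ndarray  # (3 * n_sel,)
    eigenvectors: np.ndarray  # (n_components, 3 * n_sel), rows orthonormal
    eigenvalues: np.ndarray  # (n_components,), Å², descending
    atom_ids: np.ndarray  # selection the basis lives on

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass
class FunctionalMode:
    """Fitted FMA model with its cross-validation metrics."""

    basis: PCABasis
    coefficients: np.ndarray  # β, functional units per Å of projection
    intercept: float
    build_range: tuple[int, int]
    r_build: float
    mcm_vector: np.ndarray  # unit norm, (3 * n_sel,)
    ewmcm_vector: np.ndarray  # unit norm, eigenvalue-weighted
    validation_range: tuple[int, int] | None = None
    r_validation: float | None = None
    mi_validation: float | None = None
    metadata: dict = field(default_factory=dict)

    def predict(self, traj: Trajectory, frames: slice | np.ndarray) -> np.ndarray:
        proj = _projections(traj, self.basis)[frames]
        return proj @ self.coefficients + self.intercept


def time_range_to_frames(traj: Trajectory, t_start: float, t_end: float) -> tuple[int, int]:
    """Convert a [t_start, t_end) time window (ns) to a frame-index range."""
    lo = int(np.searchsorted(traj.times, t_start, side="left"))
    hi = int(np.searchsorted(traj.times, t_end, side="left"))
    if hi <= lo:
        raise DataError(f"time window [{t_start}, {t_end}) ns selects no frames")
    return lo, hi


def _flatten(traj: Trajectory, atom_ids: np.ndarray) -> np.ndarray:
    return traj.coordinates[:, atom_ids].reshape(traj.n_frames, -1)


def _apply_exclusions(traj: Trajectory, selection: AtomSelection, exclude_residue_ranges):
    ids = selection.ids
    if not exclude_residue_ranges:
        return ids
    resid = np.asarray(traj.topology.residue_indices)[ids]
    keep = np.ones(ids.size, dtype=bool)
    for lo, hi in exclude_residue_ranges:
        keep &= ~((resid >= lo) & (resid <= hi))
    return ids[keep]


def pca_backbone(
    traj: Trajectory,
    analysis_selection: AtomSelection,
    n_components: int = 50,
    exclude_residue_ranges=None,
    frames: slice | None = None,
) -> PCABasis:
    """PCA of the flattened selection coordinates.

    The trajectory should already be superposed on the same selection so
    that rigid-body motion does not contaminate the covariance.  Flexible
    residue ranges (e.g. loops, termini) can be excluded.  ``n_components``
    is clipped (with a warning) if it exceeds the coordinate rank.
    """
    ids = _apply_exclusions(traj, analysis_selection, exclude_residue_ranges)
    if ids.size == 0:
        raise DataError("analysis selection empty after exclusions")
    X = _flatten(traj, ids)
    if frames is not None:
        X = X[frames]
    mean = X.mean(axis=0)
    Xc = X - mean
    max_rank = min(Xc.shape[0] - 1 if Xc.shape[0] > 1 else 1, Xc.shape[1])
    if n_components > 3 * ids.size or n_components > max_rank:
        clipped = min(3 * ids.size, max_rank)
        warnings.warn(f"n_components={n_components} exceeds rank; clipped to {clipped}", stacklevel=2)
        n_components = clipped
    # SVD of the centred data matrix: eigenvalues of the covariance are s² / (n-1)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    denom = max(Xc.shape[0] - 1, 1)
    eigenvalues = (s**2) / denom
    return PCABasis(
        mean_structure=mean,
        eigenvectors=Vt[:n_components],
        eigenvalues=eigenvalues[:n_components],
        atom_ids=ids,
    )


def _projections(traj: Trajectory, basis: PCABasis) -> np.ndarray:
    X = _flatten(traj, basis.atom_ids) - basis.mean_structure
    return X @ basis.eigenvectors.T


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.pearsonr(x, y).statistic)


def fma_build(
    basis: PCABasis,
    traj: Trajectory,
    functional_series: np.ndarray,
    build_range: tuple[int, int],
) -> FunctionalMode:
    """Least-squares fit of f(t) on the PCA projections over the build window."""
    f = np.asarray(functional_series, float)
    if f.size != traj.n_frames:
        raise DataError("functional series length must equal the frame count")
    lo, hi = build_range
    n_build = hi - lo
    if n_build <= basis.n_components:
        raise DataError(
            f"{n_build} build frames cannot constrain {basis.n_components} components; "
            "use fewer components or a longer build window"
        )
    proj = _projections(traj, basis)[lo:hi]
    y = f[lo:hi]
    A = np.column_stack([proj, np.ones(n_build)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    beta, intercept = coef[:-1], float(coef[-1])
    pred = proj @ beta + intercept
    r_build = pearson_r(pred, y) if np.std(pred) > 0 else 0.0

    mcm = basis.eigenvectors.T @ beta
    ew = basis.eigenvectors.T @ (beta * basis.eigenvalues)
    mcm_n = np.linalg.norm(mcm)
    ew_n = np.linalg.norm(ew)
    return FunctionalMode(
        basis=basis,
        coefficients=beta,
        intercept=intercept,
        build_range=(lo, hi),
        r_build=r_build,
        mcm_vector=mcm / mcm_n if mcm_n > 0 else mcm,
        ewmcm_vector=ew / ew_n if ew_n > 0 else ew,
    )


def fma_cross_validate(
    mode: FunctionalMode,
    traj: Trajectory,
    functional_series: np.ndarray,
    validation_range: tuple[int, int],
    mi_bins: str | int = "cbrt",
) -> tuple[float, float]:
    """Pearson R and mutual information between f and the model prediction
    on a validation window disjoint from the build window."""
    lo, hi = validation_range
    if hi <= lo:
        raise DataError("empty validation range")
    b_lo, b_hi = mode.build_range
    if lo < b_hi and b_lo < hi:
        raise DataError("validation range overlaps the build range")
    f = np.asarray(functional_series, float)[lo:hi]
    pred = mode.predict(traj, slice(lo, hi))
    r = pearson_r(f, pred)
    mi = mutual_information(f, pred, bins=mi_bins)
    mode.validation_range = (lo, hi)
    mode.r_validation = r
    mode.mi_validation = mi
    return r, mi


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------


def _fd_bin_count(x: np.ndarray) -> int:
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0:
        return 1
    width = 2.0 * iqr * x.size ** (-1.0 / 3.0)
    return max(1, int(np.ceil((x.max() - x.min()) / width)))


def mutual_information(x, y, bins: str | int = "cbrt", estimator: str = "hist") -> float:
    """Mutual information between two series, in nats.

    ``estimator="hist"``: equal-width histogram on each marginal with the
    Miller–Madow small-sample bias correction applied to each entropy.
    The default bin count is max(8, n^(1/3)) per marginal ("cbrt"), which
    keeps the joint histogram well populated; the larger Freedman–Diaconis
    count ("fd") and fixed integers are also accepted but carry noticeably
    more positive bias in the joint term.  With this estimator MI(x, x)
    equals the (bias-corrected) entropy of binned x.  ``estimator="knn"``
    delegates to scikit-learn's nearest-neighbour estimator.

    A constant input yields 0 with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 100:
        raise DataError("series must have equal length >= 100")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series: mutual information is 0", stacklevel=2)
        return 0.0
    if estimator == "knn":
        from sklearn.feature_selection import mutual_info_regression

        return float(mutual_info_regression(x[:, None], y, random_state=0)[0])
    if estimator != "hist":
        raise DataError(f"unknown MI estimator {estimator!r}")

    n = x.size
    if bins == "cbrt":
        kx = ky = max(8, int(round(n ** (1.0 / 3.0))))
    elif bins == "fd":
        kx, ky = _fd_bin_count(x), _fd_bin_count(y)
    else:
        kx = ky = int(bins)
    cxy, _, _ = np.histogram2d(x, y, bins=[kx, ky])
    cx = cxy.sum(axis=1)
    cy = cxy.sum(axis=0)

    def h_mm(counts):
        p = counts[counts > 0] / n
        occupied = p.size
        return -np.sum(p * np.log(p)) + (occupied - 1) / (2.0 * n)

    return float(h_mm(cx) + h_mm(cy) - h_mm(cxy.ravel()))


def project_mode_on_structure(mode: FunctionalMode) -> np.ndarray:
    """Per-atom magnitude of the unit ewMCM displacement.

    The squared weights sum to 1, so a single-atom mode gives that atom a
    weight of exactly 1; use for colouring structures or ranking residues
    by their participation in the correlated motion.
    """
    per_atom = mode.ewmcm_vector.reshape(-1, 3)
    return np.linalg.norm(per_atom, axis=1)
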