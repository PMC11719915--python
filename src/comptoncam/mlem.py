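"""List-mode MLEM reconstruction with a Gaussian cone-surface system model.

Each Compton event constrains its source to a cone (apex at the scatter
point, axis from absorber through scatterer, half-angle from the
deposited energies).  The system-matrix element ``h_db`` for event ``d``
and voxel ``b`` is modelled as a Gaussian in the angular distance of the
voxel from the cone surface times an inverse-square geometric factor,

    h_db ∝ exp(-δ²/(2σ²)) / ||x_b − apex_d||²,

truncated beyond ``cutoff·σ`` and normalized to unit row sum.  This is
the standard cone-surface kernel for list-mode Compton reconstruction;
the angular width σ defaults to the propagated cone-angle uncertainty of
each event for a 5 keV energy-resolution surrogate.

The maximum-likelihood iteration, in list mode (every occupied detector
bin holds a single count), is

    f_b ← (f_b / s_b) · Σ_d  h_db / (Σ_b' h_db' f_b'),

with the sensitivity ``s_b`` the total detection probability from voxel
``b`` (uniform by default — a good approximation for a small, distant
detector — or a Monte-Carlo solid-angle estimate).  A dense binned-mode
iteration is provided as an equivalence oracle for small instances: with
singleton bins and consistent sensitivity the two updates coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import ndimage

from .detector import DetectorGeometry
from .grids import GridSpec, ImageVolume
from .kinematics import angular_uncertainty, scattering_angle_or_nan
from .phantoms import make_body_cylinder
from .simulate import EventList

__all__ = [
    "ConeModel",
    "cone_from_event",
    "system_matrix_row",
    "build_system_matrix",
    "sensitivity_map",
    "ListModeMLEM",
    "MLEMResult",
    "lm_mlem_reconstruct",
    "binned_mlem_reconstruct",
    "default_reconstruction_mask",
]


@dataclass(frozen=True)
class ConeModel:
    """Width and support of the Gaussian cone-surface kernel.

    ``angular_sigma=None`` uses each event's propagated angular
    uncertainty at ``energy_resolution_mev``; a float fixes one global
    width (rad).  ``cutoff`` truncates the kernel at that many sigmas.
    """

    angular_sigma: float | None = None
    cutoff: float = 3.0
    energy_resolution_mev: float = 0.005
    fallback_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.angular_sigma is not None and self.angular_sigma <= 0:
            raise ValueError("angular_sigma must be positive")
        if self.cutoff < 3:
            raise ValueError("cutoff must be >= 3 sigma")

    def sigmas(self, e_total: np.ndarray, e1: np.ndarray) -> np.ndarray:
        """Per-event kernel width (rad)."""
        if self.angular_sigma is not None:
            return np.full(np.shape(e1), self.angular_sigma, dtype=float)
        out = np.full(np.shape(e1), self.fallback_sigma, dtype=float)
        with np.errstate(all="ignore"):
            theta = scattering_angle_or_nan(e_total, e1)
            ok = np.isfinite(theta) & (np.sin(theta) > 1e-6)
            sig = np.where(
                ok,
                0.511 * self.energy_resolution_mev
                / (np.where(ok, np.sin(theta), 1.0)
                   * (np.asarray(e_total) - np.asarray(e1)) ** 2),
                self.fallback_sigma,
            )
        # keep widths in a sane band; degenerate angles fall back
        return np.clip(np.where(ok, sig, self.fallback_sigma), 1e-3, 0.5)


def cone_from_event(d1, d2, e1, e2):
    """Compton cone parameters (apex, axis, half-angle) for events.

    Vectorized over leading dimensions; kinematically forbidden events
    get a NaN half-angle so callers can reject and count them.  The axis
    points from the absorber through the scatterer, toward the source
    side of the cone.
    """
    d1 = np.atleast_2d(np.asarray(d1, float))
    d2 = np.atleast_2d(np.asarray(d2, float))
    e1 = np.atleast_1d(np.asarray(e1, float))
    e2 = np.atleast_1d(np.asarray(e2, float))
    axis = d1 - d2
    norms = np.linalg.norm(axis, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("coincident interaction points")
    axis = axis / norms
    half_angle = scattering_angle_or_nan(e1 + e2, e1)
    return d1, axis, half_angle


def default_reconstruction_mask(
    grid: GridSpec, radius: float = 30.0, height: float = 100.0
) -> np.ndarray:
    """Body cylinder dilated by one voxel; voxels outside stay at zero."""
    body = make_body_cylinder(grid, radius, height).values > 0
    return ndimage.binary_dilation(body)


def _rows_for_chunk(apex, axis, half_angle, sigma, centers, cutoff, mask_flat):
    """Sparse kernel rows for a chunk of events (dense angular sweep)."""
    r = centers[None, :, :] - apex[:, None, :]
    dist = np.linalg.norm(r, axis=2)
    dist = np.maximum(dist, 1e-6)
    cosang = np.einsum("evk,ek->ev", r, axis) / dist
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    delta = np.abs(ang - half_angle[:, None])
    inside = (delta <= cutoff * sigma[:, None]) & mask_flat[None, :]
    h = np.where(
        inside, np.exp(-0.5 * (delta / sigma[:, None]) ** 2) / dist**2, 0.0
    )
    return h


def system_matrix_row(
    d1, d2, e1, e2, grid: GridSpec, model: ConeModel, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse system-matrix row (indices, weights) for one event.

    Weights are non-negative and sum to one; an all-zero row (cone
    missing the masked region, or forbidden kinematics) returns empty
    arrays, signalling that the event should be dropped.
    """
    mask_flat = (
        np.ones(grid.n_voxels, bool) if mask is None else np.asarray(mask).ravel()
    )
    apex, axis, half = cone_from_event(d1, d2, e1, e2)
    if np.isnan(half[0]):
        return np.empty(0, int), np.empty(0)
    sigma = model.sigmas(np.asarray(e1 + e2, float), np.asarray(e1, float))
    sigma = np.atleast_1d(sigma)
    h = _rows_for_chunk(
        apex, axis, half, sigma, grid.voxel_centers(), model.cutoff, mask_flat
    )[0]
    idx = np.nonzero(h)[0]
    if idx.size == 0:
        return np.empty(0, int), np.empty(0)
    w = h[idx]
    return idx, w / w.sum()


def build_system_matrix(
    events: EventList,
    grid: GridSpec,
    model: ConeModel,
    mask: np.ndarray | None = None,
    chunk: int = 64,
) -> tuple[sp.csr_matrix, int]:
    """Assemble the (n_events x n_voxels) sparse system matrix.

    Returns the matrix and the number of dropped events (forbidden
    kinematics or empty rows); dropped events do not appear as rows.
    """
    mask_flat = (
        np.ones(grid.n_voxels, bool) if mask is None else np.asarray(mask).ravel()
    )
    centers = grid.voxel_centers()
    apex, axis, half = cone_from_event(events.d1, events.d2, events.e1, events.e2)
    sigma = model.sigmas(events.total_energy, events.e1)
    valid = np.isfinite(half)
    n_dropped = int(np.count_nonzero(~valid))

    indptr = [0]
    indices: list[np.ndarray] = []
    data: list[np.ndarray] = []
    vidx = np.nonzero(valid)[0]
    for s in range(0, vidx.size, chunk):
        ii = vidx[s : s + chunk]
        h = _rows_for_chunk(
            apex[ii], axis[ii], half[ii], sigma[ii], centers, model.cutoff, mask_flat
        )
        sums = h.sum(axis=1)
        for row, tot in zip(h, sums):
            if tot <= 0:
                n_dropped += 1
                continue
            nz = np.nonzero(row)[0]
            indices.append(nz)
            data.append(row[nz] / tot)
            indptr.append(indptr[-1] + nz.size)
    if indices:
        H = sp.csr_matrix(
            (np.concatenate(data), np.concatenate(indices), np.array(indptr)),
            shape=(len(indptr) - 1, grid.n_voxels),
        )
    else:
        H = sp.csr_matrix((0, grid.n_voxels))
    return H, n_dropped


def sensitivity_map(
    grid: GridSpec,
    det: DetectorGeometry | None = None,
    mode: str = "uniform",
    n_directions: int = 256,
    rng: np.random.Generator | int = 0,
    floor: float = 1e-6,
) -> ImageVolume:
    """Detection sensitivity ``s_b`` per voxel.

    ``uniform`` returns a constant map (the small-detector limit where
    the subtended solid angle is essentially the same everywhere);
    ``solid_angle`` Monte-Carlo-estimates the fraction of isotropic
    directions from each voxel that meet any crystal, floor-clamped so
    the MLEM division stays defined.
    """
    if mode == "uniform":
        return ImageVolume(grid, np.ones(grid.shape))
    if mode != "solid_angle":
        raise ValueError(f"unknown sensitivity mode {mode!r}")
    if det is None:
        raise ValueError("solid_angle mode needs a detector geometry")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    centers = grid.voxel_centers()
    cos_t = rng.uniform(-1.0, 1.0, n_directions)
    phi = rng.uniform(0.0, 2.0 * np.pi, n_directions)
    sin_t = np.sqrt(1.0 - cos_t**2)
    dirs = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    hits = np.zeros(centers.shape[0])
    for d in dirs:
        dd = np.broadcast_to(d, centers.shape)
        any_hit = np.zeros(centers.shape[0], bool)
        for slab in det.crystals:
            lo, hi = slab.ray_intersect(centers, dd)
            any_hit |= hi > np.maximum(lo, 0.0)
        hits += any_hit
    s = np.maximum(hits / n_directions, floor)
    return ImageVolume(grid, s.reshape(grid.shape))


# --------------------------------------------------------------------------
# model / results objects


@dataclass
class MLEMResult:
    """Outcome of a list-mode MLEM fit.

    Attributes
    ----------
    image : ImageVolume
        The final iterate.
    snapshots : dict[int, ImageVolume]
        Requested intermediate iterates (e.g. iterations 10 and 60).
    n_iter : int
        Iterations applied.
    n_events, n_dropped_events : int
        Events used / rejected while building the system matrix.
    loglikelihood : list[float]
        List-mode Poisson log-likelihood after each iteration
        (``Σ_d log(H f)_d − Σ_b s_b f_b``); non-decreasing for EM.
    skipped_event_counts : list[int]
        Events with a zero forward projection, per iteration.
    nmse_history : list[float]
        Per-iteration NMSE against the optional ``reference`` volume
        passed to :meth:`ListModeMLEM.fit`.
    """

    image: ImageVolume
    snapshots: dict[int, ImageVolume]
    n_iter: int
    n_events: int
    n_dropped_events: int
    loglikelihood: list[float] = field(default_factory=list)
    skipped_event_counts: list[int] = field(default_factory=list)
    nmse_history: list[float] = field(default_factory=list)

    def iteration_log(self):
        """Per-iteration diagnostics as a DataFrame (for CSV export)."""
        import pandas as pd

        n = self.n_iter
        data = {"iteration": np.arange(1, n + 1)}
        if self.skipped_event_counts:
            data["skipped_events"] = self.skipped_event_counts
        if self.loglikelihood:
            data["loglikelihood"] = self.loglikelihood
        if self.nmse_history:
            data["nmse_vs_reference"] = self.nmse_history
        return pd.DataFrame(data)

    def summary(self) -> str:
        lines = [
            "List-mode MLEM reconstruction",
            "=" * 34,
            f"grid:            {self.image.grid.shape}",
            f"events used:     {self.n_events}",
            f"events dropped:  {self.n_dropped_events}",
            f"iterations:      {self.n_iter}",
            f"snapshots:       {sorted(self.snapshots)}",
        ]
        if self.loglikelihood:
            lines.append(f"final loglik:    {self.loglikelihood[-1]:.6g}")
        mx = self.image.values.max()
        lines.append(f"max intensity:   {mx:.6g}")
        return "\n".join(lines)


class ListModeMLEM:
    """List-mode MLEM as a fittable model.

    Parameters
    ----------
    events : EventList
        Detected (energy-windowed) Compton events.
    grid : GridSpec
        Reconstruction grid.
    cone_model : ConeModel, optional
        Kernel width/support configuration.
    sensitivity : "uniform" | ImageVolume | ndarray
        Per-voxel detection probability ``s_b``.
    mask : ndarray of bool, optional
        Reconstruction support; defaults to the body cylinder dilated by
        one voxel.  Voxels outside stay at zero.
    """

    def __init__(
        self,
        events: EventList,
        grid: GridSpec,
        cone_model: ConeModel | None = None,
        sensitivity="uniform",
        mask: np.ndarray | None = None,
    ) -> None:
        self.grid = grid
        self.cone_model = cone_model or ConeModel()
        self.mask = (
            default_reconstruction_mask(grid) if mask is None else np.asarray(mask, bool)
        )
        if isinstance(sensitivity, str):
            if sensitivity != "uniform":
                raise ValueError("string sensitivity must be 'uniform'")
            self.sensitivity = np.ones(grid.n_voxels)
        elif isinstance(sensitivity, ImageVolume):
            self.sensitivity = sensitivity.values.ravel().copy()
        else:
            self.sensitivity = np.asarray(sensitivity, float).ravel()
        if np.any(self.sensitivity[self.mask.ravel()] <= 0):
            raise ValueError("sensitivity must be positive inside the mask")
        self.H, self.n_dropped_events = build_system_matrix(
            events, grid, self.cone_model, self.mask
        )

    def fit(
        self,
        n_iter: int = 60,
        init: ImageVolume | None = None,
        snapshots: tuple[int, ...] = (),
        track_likelihood: bool = False,
        reference: ImageVolume | None = None,
    ) -> MLEMResult:
        """Run ``n_iter`` multiplicative EM updates.

        ``init`` defaults to 1 inside the mask; ``n_iter=0`` returns it
        unchanged.  ``snapshots`` lists iteration numbers whose iterate
        should be retained.  With a ``reference`` volume (e.g. the true
        activity map) the per-iteration NMSE against it is recorded.
        """
        if n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        mask = self.mask.ravel()
        if init is None:
            f = np.where(mask, 1.0, 0.0)
        else:
            f = init.values.ravel().astype(float).copy()
            if np.any(f[mask] <= 0):
                raise ValueError("init must be strictly positive inside the mask")
            f = np.where(mask, f, 0.0)
        H, s = self.H, self.sensitivity
        want = set(snapshots)
        snaps: dict[int, ImageVolume] = {}
        loglik: list[float] = []
        skipped: list[int] = []
        nmse_hist: list[float] = []
        ref_flat = None
        if reference is not None:
            r = reference.values.ravel()
            rng_r = r.max() - r.min()
            if rng_r <= 0:
                raise ValueError("reference volume is constant")
            ref_flat = (r - r.min()) / rng_r
        if 0 in want:
            snaps[0] = ImageVolume(self.grid, f.reshape(self.grid.shape).copy())
        for it in range(1, n_iter + 1):
            if H.shape[0] == 0:
                # no usable events: the update has no data term, keep init
                for jt in range(it, n_iter + 1):
                    if jt in want:
                        snaps[jt] = ImageVolume(
                            self.grid, f.reshape(self.grid.shape).copy()
                        )
                break
            denom = H @ f
            ok = denom > 0
            skipped.append(int(np.count_nonzero(~ok)))
            ratio = np.zeros_like(denom)
            ratio[ok] = 1.0 / denom[ok]
            back = H.T @ ratio
            f = np.where(mask, f / s * back, 0.0)
            if track_likelihood:
                denom = H @ f
                pos = denom > 0
                loglik.append(float(np.log(denom[pos]).sum() - (s * f)[mask].sum()))
            if ref_flat is not None:
                spread = f.max() - f.min()
                est = (f - f.min()) / spread if spread > 0 else f
                nmse_hist.append(
                    float(((ref_flat - est) ** 2).sum() / (ref_flat**2).sum())
                )
            if it in want:
                snaps[it] = ImageVolume(self.grid, f.reshape(self.grid.shape).copy())
        return MLEMResult(
            image=ImageVolume(self.grid, f.reshape(self.grid.shape)),
            snapshots=snaps,
            n_iter=n_iter,
            n_events=H.shape[0],
            n_dropped_events=self.n_dropped_events,
            loglikelihood=loglik,
            skipped_event_counts=skipped,
            nmse_history=nmse_hist,
        )


def lm_mlem_reconstruct(
    events: EventList,
    grid: GridSpec,
    det: DetectorGeometry | None = None,
    model: ConeModel | None = None,
    n_iter: int = 60,
    init: ImageVolume | None = None,
    snapshots: tuple[int, ...] = (),
    sensitivity="uniform",
    mask: np.ndarray | None = None,
) -> MLEMResult:
    """Functional wrapper: build a :class:`ListModeMLEM` and fit it."""
    del det  # geometry enters through the events; kept for interface symmetry
    m = ListModeMLEM(events, grid, model, sensitivity=sensitivity, mask=mask)
    return m.fit(n_iter=n_iter, init=init, snapshots=snapshots)


def binned_mlem_reconstruct(
    g: np.ndarray,
    H: np.ndarray,
    n_iter: int,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Dense binned-mode MLEM oracle for small instances.

    Applies ``f_j ← f_j / (Σ_i h_ij) · Σ_i h_ij g_i / (Σ_k h_ik f_k)``
    exactly; intended as the equivalence reference for the list-mode
    iteration (singleton bins, unit counts, consistent sensitivity).
    """
    H = np.asarray(H, float)
    g = np.asarray(g, float).ravel()
    if H.ndim != 2 or H.shape[0] != g.size:
        raise ValueError("H must be (n_bins, n_voxels) matching g")
    if H.size * 1.0 > 1e6 * 10:
        raise ValueError("binned oracle is for small instances only")
    colsum = H.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("H column sums must be positive")
    f = np.ones(H.shape[1]) if init is None else np.asarray(init, float).copy()
    if np.any(f < 0):
        raise ValueError("init must be non-negative")
    for _ in range(n_iter):
        denom = H @ f
        ratio = np.divide(g, denom, out=np.zeros_like(denom), where=denom > 0)
        f = f / colsum * (H.T @ ratio)
    return f
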