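"""Multiple-time-origin displacement-correlation estimators.

This module produces the raw material of every transport estimate: the
mean-square displacement (MSD) of selected particles, the mean-square
displacement of the itinerant dipole M(t) = sum_i q_i r_i(t) over the ions
(MSDD), and group-group cross-displacement correlations whose long-time
slopes are the Onsager coefficients.

Collective correlations are computed from per-frame group sums, which makes
the cost per lag O(n_frames) regardless of ion count and keeps the identity

    MSDD(tau) = sum_AB z_A z_B * N * C_AB(tau)

exact at machine precision (C_AB is the cross series normalised by the
total ion count N).  All accumulations run through numpy's pairwise-summing
reductions in float64, which bounds cancellation error growth for the
k^2-growing dipole terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ChargeAssignment, CorrelationSeries, OnsagerMatrix, Trajectory
from .stats import fit_linear_slope

#: origin-chunk size bounding temporary arrays in the MSD kernel
_CHUNK = 2048


@dataclass(frozen=True)
class SamplingPlan:
    """How lags and time origins are sampled.

    ``order_n_blocked`` uses the blocked (order-n) lag grid: every lag from
    1 to block_factor-1 frames, then multiples of block_factor, then of
    block_factor^2, and so on -- logarithmic coverage at linear cost.  The
    ``linear`` grid (every frame lag) exists for exact comparison against
    brute-force references.
    """

    origin_stride: int = 1
    max_lag: float | None = None        # ps; default: half the duration
    lag_grid: str = "order_n_blocked"   # or "linear"
    block_factor: int = 10

    def __post_init__(self) -> None:
        if self.origin_stride < 1:
            raise ValueError("origin_stride must be >= 1")
        if self.lag_grid not in ("order_n_blocked", "linear"):
            raise ValueError(f"unknown lag grid {self.lag_grid!r}")
        if self.block_factor < 2:
            raise ValueError("block_factor must be >= 2")

    def lag_frames(self, traj: Trajectory) -> np.ndarray:
        """Positive lag counts (in frames) admitted by this plan."""
        if traj.n_frames < 2:
            return np.array([], dtype=int)
        dt = traj.dt
        if self.max_lag is None:
            max_frames = (traj.n_frames - 1) // 2 or 1
        else:
            if self.max_lag > traj.duration:
                raise ValueError(
                    f"max_lag {self.max_lag} ps exceeds the trajectory duration "
                    f"{traj.duration} ps")
            max_frames = int(round(self.max_lag / dt))
        max_frames = min(max_frames, traj.n_frames - 1)
        if max_frames < 1:
            return np.array([], dtype=int)
        if self.lag_grid == "linear":
            return np.arange(1, max_frames + 1)
        lags = []
        scale = 1
        while scale <= max_frames:
            for m in range(1, self.block_factor):
                lag = m * scale
                if lag > max_frames:
                    break
                lags.append(lag)
            scale *= self.block_factor
        return np.unique(np.array(lags, dtype=int))


def _collective_correlation(x_a: np.ndarray, x_b: np.ndarray,
                            lags: np.ndarray, stride: int):
    """<(x_a(t+k) - x_a(t)) . (x_b(t+k) - x_b(t))> over admitted origins.

    x_a, x_b: (F, 3) collective vectors sharing the same frames.
    """
    values = np.empty(lags.size)
    counts = np.empty(lags.size, dtype=int)
    f = x_a.shape[0]
    for idx, k in enumerate(lags):
        origins = np.arange(0, f - k, stride)
        da = x_a[origins + k] - x_a[origins]
        if x_b is x_a:
            db = da
        else:
            db = x_b[origins + k] - x_b[origins]
        values[idx] = np.mean(np.sum(da * db, axis=1))
        counts[idx] = origins.size
    return values, counts


def _require_unwrapped(traj: Trajectory) -> None:
    if traj.wrapped:
        raise ValueError("correlations need unwrapped coordinates; "
                         "run unwrap_coordinates first")


def _resolve_selection(traj: Trajectory, selection) -> np.ndarray:
    """Turn a role name, species label, or boolean mask into a mask."""
    if isinstance(selection, str):
        if selection in ("cation", "anion", "solvent"):
            mask = traj.role_mask(selection)
        else:
            mask = traj.species_mask(selection)
    else:
        mask = np.asarray(selection, dtype=bool)
        if mask.shape != (traj.n_particles,):
            raise ValueError("selection mask length must match particle count")
    if not mask.any():
        raise ValueError(f"empty selection {selection!r}")
    return mask


def mean_square_displacement(traj: Trajectory, selection,
                             plan: SamplingPlan) -> CorrelationSeries:
    """MSD(tau) averaged over the selected particles and time origins (nm^2)."""
    _require_unwrapped(traj)
    mask = _resolve_selection(traj, selection)
    pos = traj.positions[:, mask, :]
    lags = plan.lag_frames(traj)
    f = pos.shape[0]
    values = np.empty(lags.size)
    counts = np.empty(lags.size, dtype=int)
    for idx, k in enumerate(lags):
        origins = np.arange(0, f - k, plan.origin_stride)
        acc = 0.0
        for s in range(0, origins.size, _CHUNK):
            o = origins[s:s + _CHUNK]
            d = pos[o + k] - pos[o]
            acc += float(np.sum(d * d))
        values[idx] = acc / (origins.size * pos.shape[1])
        counts[idx] = origins.size
    return CorrelationSeries(
        lags=np.concatenate([[0.0], lags * traj.dt]),
        values=np.concatenate([[0.0], values]),
        origin_counts=np.concatenate([[traj.n_frames], counts]),
        units="nm^2")


def dipole_series(traj: Trajectory, charges: ChargeAssignment,
                  charge_set: str) -> np.ndarray:
    """Per-frame itinerant dipole M(t) = sum_ions q_i r_i(t) in e nm."""
    q = charges.charges_for(traj, charge_set)
    return np.einsum("i,fid->fd", q, traj.positions)


def dipole_displacement_series(traj: Trajectory, charges: ChargeAssignment,
                               charge_set: str,
                               plan: SamplingPlan) -> CorrelationSeries:
    """Mean-square dipole displacement <|M(t+tau) - M(t)|^2> (e^2 nm^2).

    Solvent particles are excluded automatically (they carry zero charge in
    conductivity analyses); a non-neutral ionic charge set is rejected since
    it would make the dipole origin-dependent.
    """
    _require_unwrapped(traj)
    q = charges.charges_for(traj, charge_set)
    if abs(float(q.sum())) > 1e-9 * max(float(np.abs(q).sum()), 1.0):
        raise ValueError(
            f"{charge_set!r} charge set is not electroneutral over the ions "
            f"(sum q = {q.sum():+.3g} e)")
    m = np.einsum("i,fid->fd", q, traj.positions)
    lags = plan.lag_frames(traj)
    values, counts = _collective_correlation(m, m, lags, plan.origin_stride)
    return CorrelationSeries(
        lags=np.concatenate([[0.0], lags * traj.dt]),
        values=np.concatenate([[0.0], values]),
        origin_counts=np.concatenate([[traj.n_frames], counts]),
        units="e^2 nm^2")


def cross_displacement_series(traj: Trajectory, group_a: str, group_b: str,
                              plan: SamplingPlan) -> CorrelationSeries:
    """Group-group displacement correlation, normalised by the total ion count.

    C_AB(tau) = (1/N) sum_{i in A} sum_{j in B} <dr_i(tau) . dr_j(tau)>,
    N the total ion count.  For A = B the double sum includes the i = j
    self terms, so the charge-weighted sum of these series over all group
    pairs reconstructs the dipole series exactly.
    """
    _require_unwrapped(traj)
    mask_a = _resolve_selection(traj, group_a)
    mask_b = _resolve_selection(traj, group_b)
    n_ions = traj.n_ions
    if n_ions == 0:
        raise ValueError("trajectory contains no ions")
    s_a = traj.positions[:, mask_a, :].sum(axis=1)
    s_b = s_a if np.array_equal(mask_a, mask_b) \
        else traj.positions[:, mask_b, :].sum(axis=1)
    lags = plan.lag_frames(traj)
    values, counts = _collective_correlation(s_a, s_b, lags, plan.origin_stride)
    return CorrelationSeries(
        lags=np.concatenate([[0.0], lags * traj.dt]),
        values=np.concatenate([[0.0], values / n_ions]),
        origin_counts=np.concatenate([[traj.n_frames], counts]),
        units="nm^2")


def self_terms_dipole_series(traj: Trajectory, charges: ChargeAssignment,
                             charge_set: str,
                             plan: SamplingPlan) -> CorrelationSeries:
    """Self-terms-only restriction of the dipole series (e^2 nm^2).

    Keeps only the i = j terms of the pairwise charge-weighted double sum:
    sum_i q_i^2 <|dr_i(tau)|^2>.  This is the quantity whose slope gives
    exactly the Nernst-Einstein conductivity -- the approximation *is* the
    neglect of the i != j terms.
    """
    _require_unwrapped(traj)
    q = charges.charges_for(traj, charge_set)
    lags = plan.lag_frames(traj)
    total = np.zeros(lags.size)
    counts = None
    for label in sorted(set(sp for sp, qi in zip(traj.species, q) if qi != 0.0)):
        mask = traj.species_mask(label) & (q != 0.0)
        if not mask.any():
            continue
        qi = float(q[np.flatnonzero(mask)[0]])
        msd = mean_square_displacement(traj, mask, plan)
        total += qi**2 * mask.sum() * msd.values[1:]
        counts = msd.origin_counts
    if counts is None:
        raise ValueError("no charged particles in the selection")
    return CorrelationSeries(
        lags=np.concatenate([[0.0], lags * traj.dt]),
        values=np.concatenate([[0.0], total]),
        origin_counts=counts,
        units="e^2 nm^2")


def onsager_matrix(traj: Trajectory, plan: SamplingPlan,
                   window: tuple) -> OnsagerMatrix:
    """Onsager coefficients from long-time slopes of the cross series.

    Lambda_AB = (1/6) d/dtau C_AB(tau) fitted over ``window`` (ps); the
    cation-anion and anion-cation coefficients come from the same averaged
    series and are equal by construction.  Units: nm^2/ps (per total ion
    count).
    """
    t_min, t_max = window
    fits = {}
    for key, (a, b) in {"pp": ("cation", "cation"),
                        "pm": ("cation", "anion"),
                        "mm": ("anion", "anion")}.items():
        series = cross_displacement_series(traj, a, b, plan)
        fits[key] = fit_linear_slope(series, t_min, t_max)
    return OnsagerMatrix(
        lambda_pp=fits["pp"].slope / 6.0,
        lambda_pm=fits["pm"].slope / 6.0,
        lambda_mp=fits["pm"].slope / 6.0,
        lambda_mm=fits["mm"].slope / 6.0,
        n_ions=traj.n_ions,
        window=(float(t_min), float(t_max)),
        stderrs={k: f.slope_stderr / 6.0 for k, f in fits.items()},
    )
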