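"""Brownian-dynamics generators with analytically known transport properties.

Three modes of overdamped (position-Langevin) dynamics:

* ``free`` -- every ion diffuses independently at its prescribed D.  The
  exact conductivity then *equals* the Nernst-Einstein value, making this
  the oracle for the uncorrelated limit.
* ``rigid_pair`` -- each cation/anion pair moves as a rigid neutral
  dumbbell: the itinerant dipole is bounded, so the exact conductivity is
  zero while the NE value stays positive -- the fully correlated limit.
* ``harmonic_pair`` -- partners tethered by a harmonic spring interpolate
  between the two limits on time scales around the tether relaxation time.

The update rule is matched exactly to the Einstein relation (per-step
displacement ~ N(0, 2 D dt) per dimension), so the MSD of a free ion is
6 D tau at *every* lag -- there is no ballistic regime.  No inter-pair
interactions, no hydrodynamics, no solvent, and no periodic wrapping are
modelled; generated positions are continuous (unwrapped).

Randomness comes from the counter-based Philox generator keyed per
(seed, stream index) with disjoint index spaces for ions and pairs, so
changing particle counts or the mode never reshuffles another particle's
stream and a (seed, spec) pair fixes the trajectory bit for bit.
"""

from __future__ import annotations

import numpy as np

from .core import (
    GAS_CONSTANT_KJ_PER_MOL_K,
    NM2_PER_PS_TO_M2_PER_S,
    SyntheticSpec,
    Trajectory,
    logger,
)

CATION_LABEL = "CAT"
ANION_LABEL = "ANI"

#: Philox key-space tags keeping ion and pair streams disjoint
_TAG_ION = 0
_TAG_PAIR = 1


def _stream(seed: int, tag: int, index: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(key=np.array([seed, (tag << 48) | index],
                                      dtype=np.uint64)))


def _d_nm2_ps(d_si: float) -> float:
    return d_si / NM2_PER_PS_TO_M2_PER_S


def _assemble(spec: SyntheticSpec, positions: np.ndarray) -> Trajectory:
    n = spec.n_cations + spec.n_anions
    times = np.arange(spec.n_steps + 1) * spec.dt
    boxes = np.full((spec.n_steps + 1, 3), spec.box_edge)
    species = (CATION_LABEL,) * spec.n_cations + (ANION_LABEL,) * spec.n_anions
    roles = ("cation",) * spec.n_cations + ("anion",) * spec.n_anions
    assert positions.shape == (spec.n_steps + 1, n, 3)
    return Trajectory(times, boxes, positions, species, roles, wrapped=False)


def simulate_free_ions(spec: SyntheticSpec) -> Trajectory:
    """Independent Brownian ions; the NE-limit oracle."""
    if spec.mode != "free":
        raise ValueError("spec.mode must be 'free'")
    return _free_ion_positions(spec)


def _free_ion_positions(spec: SyntheticSpec) -> Trajectory:
    n = spec.n_cations + spec.n_anions
    pos = np.empty((spec.n_steps + 1, n, 3))
    for i in range(n):
        d = spec.d_plus if i < spec.n_cations else spec.d_minus
        sigma = np.sqrt(2.0 * _d_nm2_ps(d) * spec.dt)
        g = _stream(spec.seed, _TAG_ION, i)
        r0 = g.uniform(0.0, spec.box_edge, 3)
        if spec.n_steps:
            steps = g.normal(0.0, sigma, (spec.n_steps, 3))
            pos[:, i, :] = r0 + np.concatenate(
                [np.zeros((1, 3)), np.cumsum(steps, axis=0)])
        else:
            pos[0, i, :] = r0
    logger.info("synthetic free ions: %d+%d ions, %d steps, dt=%g ps",
                spec.n_cations, spec.n_anions, spec.n_steps, spec.dt)
    return _assemble(spec, pos)


def simulate_rigid_pairs(spec: SyntheticSpec) -> Trajectory:
    """Rigid neutral +/- dumbbells; the zero-conductivity oracle.

    Each pair's centre diffuses with the composite diffusivity
    D_c = D+ D- / (D+ + D-) (frictions add for a rigid body); the
    orientation is resampled uniformly on the sphere every frame -- the
    infinite-rotational-diffusion limit, which keeps the bond length exact
    and the ion MSD linear (centre term) plus a constant offset (rotation).
    """
    if spec.mode != "rigid_pair":
        raise ValueError("spec.mode must be 'rigid_pair'")
    n_pairs = spec.n_cations
    b = spec.pair_bond_length
    d_c = _d_nm2_ps(spec.d_plus * spec.d_minus / (spec.d_plus + spec.d_minus))
    sigma_c = np.sqrt(2.0 * d_c * spec.dt)
    f = spec.n_steps + 1
    pos = np.empty((f, 2 * n_pairs, 3))
    for p in range(n_pairs):
        g = _stream(spec.seed, _TAG_PAIR, p)
        c0 = g.uniform(0.0, spec.box_edge, 3)
        if spec.n_steps:
            centre = c0 + np.concatenate(
                [np.zeros((1, 3)),
                 np.cumsum(g.normal(0.0, sigma_c, (spec.n_steps, 3)), axis=0)])
        else:
            centre = c0[None, :]
        # uniform unit vectors: normalised Gaussians
        u = g.normal(size=(f, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pos[:, p, :] = centre + 0.5 * b * u
        pos[:, n_pairs + p, :] = centre - 0.5 * b * u
    logger.info("synthetic rigid pairs: %d dumbbells, bond %g nm, %d steps",
                n_pairs, b, spec.n_steps)
    return _assemble(spec, pos)


def simulate_correlated_ions(spec: SyntheticSpec) -> Trajectory:
    """Harmonically tethered +/- pairs interpolating free <-> rigid.

    Overdamped dynamics with a zero-rest-length spring of stiffness k
    (kJ/mol/nm^2) acting on the pair separation.  ``spring_constant = 0``
    is accepted as an alias of the free mode.  The scheme is explicit
    Euler-Maruyama; the dimensionless step mu k dt must stay below 0.5 for
    stability (raised otherwise).
    """
    if spec.mode != "harmonic_pair":
        raise ValueError("spec.mode must be 'harmonic_pair'")
    k = float(spec.spring_constant)
    if k == 0.0:
        free = SyntheticSpec(
            n_cations=spec.n_cations, n_anions=spec.n_anions,
            d_plus=spec.d_plus, d_minus=spec.d_minus,
            box_edge=spec.box_edge, dt=spec.dt, n_steps=spec.n_steps,
            mode="free", temperature=spec.temperature, seed=spec.seed)
        return _free_ion_positions(free)

    kt = GAS_CONSTANT_KJ_PER_MOL_K * spec.temperature  # kJ/mol
    n_pairs = spec.n_cations
    dp, dm = _d_nm2_ps(spec.d_plus), _d_nm2_ps(spec.d_minus)
    mu_p, mu_m = dp / kt, dm / kt  # nm^2 / (ps kJ/mol)
    step_number = max(mu_p, mu_m) * k * spec.dt
    if step_number >= 0.5:
        raise ValueError(
            f"unstable integration: mu*k*dt = {step_number:.3g} >= 0.5; "
            "reduce dt or the spring constant")
    f = spec.n_steps + 1
    pos = np.empty((f, 2 * n_pairs, 3))
    sep_std = np.sqrt(kt / k)  # equilibrium separation scale per dimension
    # draw every pair's stream up front (keyed per pair, so counts do not
    # reshuffle), then integrate all pairs per step
    rp = np.empty((n_pairs, 3))
    rm = np.empty((n_pairs, 3))
    noise_p = np.empty((spec.n_steps, n_pairs, 3))
    noise_m = np.empty((spec.n_steps, n_pairs, 3))
    for p in range(n_pairs):
        g = _stream(spec.seed, _TAG_PAIR, p)
        rp[p] = g.uniform(0.0, spec.box_edge, 3)
        rm[p] = rp[p] + g.normal(0.0, sep_std, 3)  # tether equilibrium
        noise_p[:, p, :] = g.normal(0.0, np.sqrt(2.0 * dp * spec.dt),
                                    (spec.n_steps, 3))
        noise_m[:, p, :] = g.normal(0.0, np.sqrt(2.0 * dm * spec.dt),
                                    (spec.n_steps, 3))
    pos[0, :n_pairs, :], pos[0, n_pairs:, :] = rp, rm
    for s in range(spec.n_steps):
        d = rp - rm
        rp = rp - mu_p * k * d * spec.dt + noise_p[s]
        rm = rm + mu_m * k * d * spec.dt + noise_m[s]
        pos[s + 1, :n_pairs, :], pos[s + 1, n_pairs:, :] = rp, rm
    logger.info("synthetic harmonic pairs: %d pairs, k=%g kJ/mol/nm^2, "
                "%d steps", n_pairs, k, spec.n_steps)
    return _assemble(spec, pos)


def simulate(spec: SyntheticSpec) -> Trajectory:
    """Dispatch on ``spec.mode``."""
    return {"free": simulate_free_ions,
            "rigid_pair": simulate_rigid_pairs,
            "harmonic_pair": simulate_correlated_ions}[spec.mode](spec)
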