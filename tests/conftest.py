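"""Shared fixtures and independent brute-force reference implementations.

The reference estimators here are deliberately written as explicit loops
over time origins and particle pairs -- O(F^2 N) and O(F N^2) -- so they
share no code path with the vectorised estimators they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from helfand.core import ChargeAssignment, Trajectory


@pytest.fixture
def charges() -> ChargeAssignment:
    """Scaled trajectory charges (+/-0.75 e) and integer transport charges."""
    return ChargeAssignment(pes_set={"CAT": 0.75, "ANI": -0.75},
                            dms_set={"CAT": 1.0, "ANI": -1.0})


def make_trajectory(positions, *, n_cations, n_anions, n_solvent=0,
                    dt=0.1, box=10.0, wrapped=False) -> Trajectory:
    """Assemble a Trajectory from a (F, N, 3) position array."""
    positions = np.asarray(positions, dtype=float)
    f, n, _ = positions.shape
    assert n == n_cations + n_anions + n_solvent
    species = ("CAT",) * n_cations + ("ANI",) * n_anions + ("SOL",) * n_solvent
    roles = ("cation",) * n_cations + ("anion",) * n_anions \
        + ("solvent",) * n_solvent
    return Trajectory(np.arange(f) * dt, np.full((f, 3), float(box)),
                      positions, species, roles, wrapped=wrapped)


def random_walk_trajectory(rng, n_frames, n_cations, n_anions, n_solvent=0,
                           dt=0.1, box=10.0, step=0.05) -> Trajectory:
    """Gaussian random-walk trajectory (unwrapped, no interactions)."""
    n = n_cations + n_anions + n_solvent
    steps = rng.normal(0.0, step, (n_frames - 1, n, 3))
    pos = rng.uniform(0.0, box, (1, n, 3)) + np.concatenate(
        [np.zeros((1, n, 3)), np.cumsum(steps, axis=0)])
    return make_trajectory(pos, n_cations=n_cations, n_anions=n_anions,
                           n_solvent=n_solvent, dt=dt, box=box)


# ---------------------------------------------------------------------------
# Brute-force references (all origins, explicit double loops)
# ---------------------------------------------------------------------------


def brute_msd(positions, lags_frames, mask):
    """All-origin MSD: mean over selected particles of |r(t+k) - r(t)|^2."""
    sel = positions[:, mask, :]
    f = sel.shape[0]
    out = []
    for k in lags_frames:
        acc, cnt = 0.0, 0
        for t0 in range(f - k):
            d = sel[t0 + k] - sel[t0]
            acc += float((d * d).sum())
            cnt += 1
        out.append(acc / (cnt * sel.shape[1]))
    return np.array(out)


def brute_dipole_msd(positions, q, lags_frames):
    """All-origin mean-square dipole displacement via the explicit
    pairwise double sum sum_i sum_j q_i q_j <dr_i . dr_j>."""
    f, n, _ = positions.shape
    out = []
    for k in lags_frames:
        acc, cnt = 0.0, 0
        for t0 in range(f - k):
            dr = positions[t0 + k] - positions[t0]
            for i in range(n):
                if q[i] == 0.0:
                    continue
                for j in range(n):
                    if q[j] == 0.0:
                        continue
                    acc += q[i] * q[j] * float(dr[i] @ dr[j])
            cnt += 1
        out.append(acc / cnt)
    return np.array(out)


def brute_cross(positions, mask_a, mask_b, n_ions, lags_frames):
    """All-origin group-group displacement correlation, 1/N normalised."""
    f = positions.shape[0]
    ia = np.flatnonzero(mask_a)
    ib = np.flatnonzero(mask_b)
    out = []
    for k in lags_frames:
        acc, cnt = 0.0, 0
        for t0 in range(f - k):
            dr = positions[t0 + k] - positions[t0]
            for i in ia:
                for j in ib:
                    acc += float(dr[i] @ dr[j])
            cnt += 1
        out.append(acc / (cnt * n_ions))
    return np.array(out)
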