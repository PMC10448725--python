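"""Domain types, physical constants, and unit conventions.

All intermediate quantities live in MD-native units -- lengths in nm, times
in ps, charges in units of the elementary charge ``e``, temperatures in K.
Conversion to SI happens only inside the transport estimators, at the point
where a conductivity (S/m) or diffusivity (m^2/s) is produced.  The constants
below are the single project-wide source of truth; estimators must not
redefine them.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger("helfand")

# ---------------------------------------------------------------------------
# Physical constants (2019 SI exact values) and unit conversion factors
# ---------------------------------------------------------------------------

BOLTZMANN_J_PER_K = 1.380649e-23
ELEMENTARY_CHARGE_C = 1.602176634e-19
AVOGADRO_PER_MOL = 6.02214076e23

#: molar gas constant in kJ/(mol K), used to express kT in force-field energy units
GAS_CONSTANT_KJ_PER_MOL_K = BOLTZMANN_J_PER_K * AVOGADRO_PER_MOL / 1000.0

NM_IN_M = 1e-9
PS_IN_S = 1e-12
#: 1 nm^2/ps expressed in m^2/s
NM2_PER_PS_TO_M2_PER_S = NM_IN_M**2 / PS_IN_S  # = 1e-6
#: 1 e^2 nm^2/ps expressed in C^2 m^2/s
E2NM2_PER_PS_TO_SI = ELEMENTARY_CHARGE_C**2 * NM2_PER_PS_TO_M2_PER_S

ROLES = ("cation", "anion", "solvent")

DEFAULT_MOLAR_MASSES = {
    "H2O": 18.015,
    "NaCl": 58.443,
    "KCl": 74.551,
}


# ---------------------------------------------------------------------------
# Trajectory containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Frame:
    """A single trajectory frame: time (ps), box edges (nm), positions (nm)."""

    time: float
    box: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        box = np.asarray(self.box, dtype=float)
        pos = np.asarray(self.positions, dtype=float)
        if box.shape != (3,):
            raise ValueError("box must be three orthorhombic edge lengths")
        if np.any(box <= 0):
            raise ValueError("box edges must be positive")
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        object.__setattr__(self, "box", box)
        object.__setattr__(self, "positions", pos)


#: relative tolerance on frame-spacing uniformity
DT_UNIFORMITY_RTOL = 1e-9


@dataclass
class Trajectory:
    """Ordered frames of particle positions with a uniform time step.

    Positions are stored as a dense ``(n_frames, n_particles, 3)`` array in
    nm with the origin at the box corner; no re-centering is applied, since
    displacement statistics are translation invariant.  ``wrapped`` records
    whether coordinates are folded into the primary box (formats do not
    self-describe this, so it is carried explicitly).
    """

    times: np.ndarray          # (F,) ps
    boxes: np.ndarray          # (F, 3) nm
    positions: np.ndarray      # (F, N, 3) nm
    species: tuple             # length N labels
    roles: tuple               # length N, each in ROLES
    wrapped: bool = False
    image_flags: np.ndarray | None = None  # (F, N, 3) ints, optional

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = tuple(self.species)
        self.roles = tuple(self.roles)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (n_frames, n_particles, 3)")
        f, n, _ = self.positions.shape
        if f < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.times.shape != (f,):
            raise ValueError("times length must match the frame count")
        if self.boxes.shape != (f, 3):
            raise ValueError("boxes must be (n_frames, 3)")
        if np.any(self.boxes <= 0):
            raise ValueError("box edges must be positive")
        if len(self.species) != n or len(self.roles) != n:
            raise ValueError("species/roles length must match the particle count")
        for r in self.roles:
            if r not in ROLES:
                raise ValueError(f"unknown particle role {r!r}; expected one of {ROLES}")
        if self.image_flags is not None:
            self.image_flags = np.asarray(self.image_flags)
            if self.image_flags.shape != self.positions.shape:
                raise ValueError("image_flags must match positions shape")

    # -- basic geometry -----------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing in ps (0.0 for a single-frame trajectory)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def has_uniform_dt(self, rtol: float = DT_UNIFORMITY_RTOL) -> bool:
        if self.n_frames < 3:
            return True
        steps = np.diff(self.times)
        ref = steps[0]
        if ref <= 0:
            return False
        return bool(np.all(np.abs(steps - ref) <= rtol * abs(ref) + 1e-15))

    # -- selections ---------------------------------------------------------

    def role_mask(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return np.array([r == role for r in self.roles], dtype=bool)

    def species_mask(self, label: str) -> np.ndarray:
        return np.array([s == label for s in self.species], dtype=bool)

    @property
    def ion_mask(self) -> np.ndarray:
        return self.role_mask("cation") | self.role_mask("anion")

    @property
    def n_ions(self) -> int:
        return int(self.ion_mask.sum())

    def frames(self) -> Iterator[Frame]:
        for k in range(self.n_frames):
            yield Frame(float(self.times[k]), self.boxes[k], self.positions[k])

    def with_positions(self, positions: np.ndarray, *, wrapped: bool,
                       image_flags: np.ndarray | None = None) -> "Trajectory":
        return Trajectory(self.times.copy(), self.boxes.copy(), positions,
                          self.species, self.roles, wrapped=wrapped,
                          image_flags=image_flags)


# ---------------------------------------------------------------------------
# Charges, composition, thermodynamic state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChargeAssignment:
    """Per-species charges (units of e) under two named sets.

    ``pes_set`` holds the (possibly scaled) charges that generated the
    trajectory -- the potential-energy-surface charges -- and ``dms_set``
    the charges transported in response to a field -- the dipole-moment-
    surface charges, formal integer values for simple salts.  Conductivity
    estimators select one set by name; solvent species always contribute
    zero charge to conductivity analyses regardless of the table entry.
    """

    pes_set: Mapping[str, float]
    dms_set: Mapping[str, float]

    def get_set(self, name: str) -> Mapping[str, float]:
        if name == "pes":
            return self.pes_set
        if name == "dms":
            return self.dms_set
        raise ValueError(f"unknown charge set {name!r}; expected 'pes' or 'dms'")

    def charges_for(self, traj: Trajectory, charge_set: str) -> np.ndarray:
        """Per-particle charge array (e); solvent particles are forced to 0."""
        table = self.get_set(charge_set)
        q = np.zeros(traj.n_particles)
        for i, (sp, role) in enumerate(zip(traj.species, traj.roles)):
            if role == "solvent":
                continue
            try:
                q[i] = table[sp]
            except KeyError:
                raise KeyError(
                    f"species {sp!r} has no charge in the {charge_set!r} set"
                ) from None
        return q

    def is_neutral(self, traj: Trajectory, charge_set: str,
                   tol: float = 1e-9) -> bool:
        return abs(float(self.charges_for(traj, charge_set).sum())) <= tol


@dataclass(frozen=True)
class SystemComposition:
    """Molecule counts and molar masses of a water + 1:1-salt system."""

    n_water: int
    n_salt: int
    molar_mass_water: float = DEFAULT_MOLAR_MASSES["H2O"]
    molar_mass_salt: float = DEFAULT_MOLAR_MASSES["NaCl"]

    def __post_init__(self) -> None:
        if self.n_water < 0 or self.n_salt < 0:
            raise ValueError("molecule counts must be >= 0")
        if self.molar_mass_water <= 0 or self.molar_mass_salt <= 0:
            raise ValueError("molar masses must be positive")

    @property
    def total_mass_kg(self) -> float:
        grams = (self.n_water * self.molar_mass_water
                 + self.n_salt * self.molar_mass_salt) / AVOGADRO_PER_MOL
        return grams * 1e-3


@dataclass(frozen=True)
class ThermoState:
    """Thermodynamic inputs of an analysis: T (K), V (nm^3), optional
    density (kg/m^3) and shear viscosity (mPa s).

    Viscosity is a user-supplied number (required only for the hydrodynamic
    finite-size correction); it is never computed here.
    """

    temperature: float
    volume: float
    density: float | None = None
    viscosity: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.viscosity is not None and self.viscosity <= 0:
            raise ValueError("viscosity must be positive when given")

    @property
    def volume_m3(self) -> float:
        return self.volume * NM_IN_M**3

    @property
    def kt_joule(self) -> float:
        return BOLTZMANN_J_PER_K * self.temperature


# ---------------------------------------------------------------------------
# Correlation and result containers
# ---------------------------------------------------------------------------


@dataclass
class CorrelationSeries:
    """Lag-indexed averaged displacement correlation.

    ``lags`` start at 0 ps and increase strictly; for displacement-type
    correlations the value at lag 0 is exactly 0.  ``origin_counts`` records
    how many time origins entered each average.  Units of ``values`` are
    nm^2 for particle displacements and e^2 nm^2 for dipole displacements,
    recorded in ``units``.
    """

    lags: np.ndarray
    values: np.ndarray
    origin_counts: np.ndarray
    units: str = "nm^2"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.origin_counts = np.asarray(self.origin_counts, dtype=int)
        if not (self.lags.shape == self.values.shape == self.origin_counts.shape):
            raise ValueError("lags, values and origin_counts must have equal length")
        if self.lags.size == 0 or self.lags[0] != 0.0:
            raise ValueError("lag grid must start at 0")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.values[0] != 0.0:
            raise ValueError("displacement correlation must vanish at lag 0")
        if np.any(self.origin_counts < 1):
            raise ValueError("every reported lag needs at least one origin")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"lag_ps": self.lags, "value": self.values,
                             "origin_count": self.origin_counts})

    def window_mask(self, t_min: float, t_max: float) -> np.ndarray:
        return (self.lags >= t_min) & (self.lags <= t_max)


@dataclass(frozen=True)
class OnsagerMatrix:
    """Cation/anion displacement-correlation coefficients (nm^2/ps).

    Normalisation: each coefficient is 1/6 of the long-time slope of the
    group-group displacement correlation divided by the *total* ion count N,
    so that sum_AB z_A z_B Lambda_AB times N e^2/(V kT) reproduces the
    dipole-route conductivity identically.  The +- and -+ entries come from
    the same averaged series and are equal by construction.
    """

    lambda_pp: float
    lambda_pm: float
    lambda_mp: float
    lambda_mm: float
    n_ions: int
    window: tuple = (0.0, 0.0)
    stderrs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        scale = max(abs(self.lambda_pm), abs(self.lambda_mp), 1e-300)
        if abs(self.lambda_pm - self.lambda_mp) > 1e-12 * scale:
            raise ValueError("lambda_pm and lambda_mp must agree (same series)")


@dataclass(frozen=True)
class TransportEstimate:
    """A physical transport value with units, uncertainty and provenance."""

    value: float
    uncertainty: float
    units: str                      # "S/m" or "m^2/s"
    method: str                     # e.g. EH_dipole, EH_onsager, NE, NE_YH, ...
    fit_window: tuple = (0.0, 0.0)  # (t_min, t_max) ps; (0, 0) for closed forms
    n_replicates: int = 1
    approximate: bool = False
    diagnostics: Mapping[str, float] = field(default_factory=dict)

    VALID_METHODS = ("EH_dipole", "EH_onsager", "NE", "NE_YH", "NE_YH_scaled",
                     "Einstein_D", "Einstein_D_YH")

    def __post_init__(self) -> None:
        if self.method not in self.VALID_METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")
        if not (self.uncertainty >= 0 or math.isnan(self.uncertainty)):
            raise ValueError("uncertainty must be >= 0")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "value": self.value,
            "uncertainty": self.uncertainty,
            "units": self.units,
            "window_ps": list(self.fit_window),
            "n_replicates": self.n_replicates,
            "approximate": self.approximate,
            "diagnostics": dict(self.diagnostics),
        }


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic Brownian-ion trajectory.

    Diffusivities are given in SI (m^2/s) and converted internally;
    ``mode`` selects free ions, rigidly bonded +/- dumbbells, or
    harmonically tethered pairs.  ``temperature`` enters only through the
    harmonic drift (spring constant in kJ/mol/nm^2).
    """

    n_cations: int
    n_anions: int
    d_plus: float         # m^2/s
    d_minus: float        # m^2/s
    box_edge: float       # nm
    dt: float             # ps
    n_steps: int
    mode: str = "free"    # free | rigid_pair | harmonic_pair
    spring_constant: float | None = None   # kJ/mol/nm^2 (harmonic mode)
    pair_bond_length: float | None = None  # nm (rigid mode)
    temperature: float = 298.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cations <= 0 or self.n_anions <= 0:
            raise ValueError("ion counts must be positive")
        if self.d_plus <= 0 or self.d_minus <= 0:
            raise ValueError("diffusivities must be positive")
        if self.box_edge <= 0:
            raise ValueError("box edge must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.mode not in ("free", "rigid_pair", "harmonic_pair"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "rigid_pair":
            if self.n_cations != self.n_anions:
                raise ValueError("rigid_pair mode needs equal cation/anion counts")
            if not self.pair_bond_length or self.pair_bond_length <= 0:
                raise ValueError("rigid_pair mode needs a positive pair_bond_length")
        if self.mode == "harmonic_pair":
            if self.n_cations != self.n_anions:
                raise ValueError("harmonic_pair mode needs equal cation/anion counts")
            if self.spring_constant is None or self.spring_constant < 0:
                raise ValueError("harmonic_pair mode needs spring_constant >= 0")


# ---------------------------------------------------------------------------
# System validation
# ---------------------------------------------------------------------------


def validate_system(traj: Trajectory, charges: ChargeAssignment) -> list:
    """Check a trajectory/charge pairing against the model's assumptions.

    Returns a list of human-readable violation strings; an empty list means
    the system is valid.  This is a reporting operation -- it never raises.
    """
    violations: list = []

    if not traj.has_uniform_dt():
        violations.append("non-uniform frame spacing")

    n_cat = int(traj.role_mask("cation").sum())
    n_an = int(traj.role_mask("anion").sum())
    if (n_cat > 0 or n_an > 0) and n_cat != n_an:
        violations.append(
            f"unequal ion counts for a 1:1 electrolyte ({n_cat} cations, {n_an} anions)"
        )

    for set_name in ("pes", "dms"):
        try:
            q = charges.charges_for(traj, set_name)
        except KeyError as exc:
            violations.append(f"{set_name} charge set: {exc.args[0]}")
            continue
        if abs(float(q.sum())) > 1e-9:
            violations.append(
                f"electroneutrality violated in {set_name} set (sum q = {q.sum():+.3g} e)"
            )
        # 1:1 restriction: one uniform magnitude on each ion side
        table = charges.get_set(set_name)
        ion_mags = set()
        for sp, role in zip(traj.species, traj.roles):
            if role in ("cation", "anion") and sp in table:
                ion_mags.add(round(abs(table[sp]), 12))
        if len(ion_mags) > 1:
            violations.append(
                f"{set_name} set mixes charge magnitudes {sorted(ion_mags)}; "
                "only symmetric 1:1 electrolytes are supported"
            )
        # solvent entries, if present, must be zero
        for sp, role in zip(traj.species, traj.roles):
            if role == "solvent" and table.get(sp, 0.0) != 0.0:
                violations.append(
                    f"solvent species {sp!r} carries nonzero {set_name} charge"
                )
                break

    return violations


# ---------------------------------------------------------------------------
# Configuration file
# ---------------------------------------------------------------------------

_KNOWN_CONFIG_KEYS = {
    "temperature_K", "viscosity_mPas", "fit_window_ps", "dt_ps", "wrapped",
    "charges_pes", "charges_dms", "molar_mass_water", "molar_mass_salt",
    "format", "origin_stride", "max_lag_ps", "lag_grid",
}


def load_config(path) -> dict:
    """Load a flat key-value YAML configuration file.

    Unknown keys raise (silently ignored settings are how dt errors corrupt
    every slope); charge maps are returned as plain dicts.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a flat key-value mapping")
    unknown = set(cfg) - _KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "fit_window_ps" in cfg:
        win = cfg["fit_window_ps"]
        if not (isinstance(win, (list, tuple)) and len(win) == 2):
            raise ValueError("fit_window_ps must be a [t_min, t_max] pair")
        cfg["fit_window_ps"] = (float(win[0]), float(win[1]))
    return cfg


def charge_assignment_from_config(cfg: Mapping) -> ChargeAssignment:
    return ChargeAssignment(pes_set=dict(cfg.get("charges_pes", {})),
                            dms_set=dict(cfg.get("charges_dms", {})))
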