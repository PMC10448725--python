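"""Plain-text trajectory readers/writers and periodic-boundary unwrapping.

Three dialects are supported, all with lengths in nm and orthorhombic boxes:

* ``xyz_ext`` -- extended XYZ with a ``Lattice="..." Time=..`` comment line;
* ``gro_seq`` -- a concatenated sequence of GRO-style frames (fixed 20-char
  atom headers, whitespace coordinates at full precision, box on the last
  line of each frame);
* ``lammps_dump`` -- LAMMPS text dump with ``ITEM: ATOMS id type x y z
  [ix iy iz]``, id-sorted on read.  This dialect carries step numbers, not
  times, so ``dt`` must be supplied.

None of the formats self-describe whether coordinates are wrapped; the
caller states it.  A conflict between file timestamps and a caller-supplied
dt is an error, never a warning: a silently wrong dt corrupts every slope
downstream.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .core import DT_UNIFORMITY_RTOL, ROLES, Trajectory, logger

SUPPORTED_FORMATS = ("xyz_ext", "gro_seq", "lammps_dump")

#: significant digits written for every numeric field
_FMT = "%.10g"


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        loc = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{loc}")


def _resolve_topology(labels, topology):
    """Map file labels to roles via the topology table.

    ``topology`` maps the label appearing in the file (species name or a
    LAMMPS numeric type as a string) to a role in {cation, anion, solvent}.
    """
    roles = []
    for lab in labels:
        try:
            role = topology[lab]
        except KeyError:
            raise KeyError(
                f"species/type {lab!r} missing from the topology table"
            ) from None
        if role not in ROLES:
            raise ValueError(f"topology maps {lab!r} to unknown role {role!r}")
        roles.append(role)
    return tuple(roles)


# ---------------------------------------------------------------------------
# Extended XYZ
# ---------------------------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([-+0-9.eE]+)")


def _read_xyz(path):
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise TrajectoryParseError("expected an atom count", i + 1)
        if i + 1 >= len(lines):
            raise TrajectoryParseError("missing comment line", i + 2)
        comment = lines[i + 1]
        m = _LATTICE_RE.search(comment)
        if m is None:
            raise TrajectoryParseError("missing Lattice=\"...\" box entry", i + 2)
        cell = np.array([float(x) for x in m.group(1).split()])
        if cell.size != 9:
            raise TrajectoryParseError("Lattice must have 9 components", i + 2)
        cell = cell.reshape(3, 3)
        off = cell - np.diag(np.diag(cell))
        if np.any(off != 0):
            raise TrajectoryParseError(
                "triclinic cell not supported (off-diagonal lattice entries)", i + 2)
        box = np.diag(cell).astype(float)
        mt = _TIME_RE.search(comment)
        time = float(mt.group(1)) if mt else None
        labels, pos = [], []
        for j in range(n):
            k = i + 2 + j
            if k >= len(lines):
                raise TrajectoryParseError("truncated frame", len(lines))
            parts = lines[k].split()
            if len(parts) < 4:
                raise TrajectoryParseError("atom record needs species + 3 coords", k + 1)
            labels.append(parts[0])
            try:
                pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise TrajectoryParseError("non-numeric coordinate", k + 1)
        frames.append((time, box, labels, np.array(pos), None))
        i += 2 + n
    return frames


def _write_xyz(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            b = traj.boxes[k]
            lattice = " ".join(
                _FMT % v for v in
                (b[0], 0, 0, 0, b[1], 0, 0, 0, b[2]))
            fh.write(f"{traj.n_particles}\n")
            fh.write(f'Lattice="{lattice}" Properties=species:S:1:pos:R:3 '
                     f"Time={_FMT % traj.times[k]}\n")
            for sp, xyz in zip(traj.species, traj.positions[k]):
                fh.write(f"{sp} {_FMT % xyz[0]} {_FMT % xyz[1]} {_FMT % xyz[2]}\n")


# ---------------------------------------------------------------------------
# GRO-like frame sequence
# ---------------------------------------------------------------------------

_GRO_TIME_RE = re.compile(r"t=\s*([-+0-9.eE]+)")


def _read_gro(path):
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        mt = _GRO_TIME_RE.search(title)
        time = float(mt.group(1)) if mt else None
        try:
            n = int(lines[i + 1].split()[0])
        except (IndexError, ValueError):
            raise TrajectoryParseError("expected an atom count", i + 2)
        labels, pos = [], []
        for j in range(n):
            k = i + 2 + j
            if k >= len(lines):
                raise TrajectoryParseError("truncated frame", len(lines))
            line = lines[k]
            if len(line) < 21:
                raise TrajectoryParseError("atom record too short", k + 1)
            resname = line[5:10].strip()
            coords = line[20:].split()
            if len(coords) < 3:
                raise TrajectoryParseError("atom record needs 3 coordinates", k + 1)
            labels.append(resname)
            try:
                pos.append([float(c) for c in coords[:3]])
            except ValueError:
                raise TrajectoryParseError("non-numeric coordinate", k + 1)
        k = i + 2 + n
        if k >= len(lines):
            raise TrajectoryParseError("missing box line", len(lines))
        boxvals = [float(x) for x in lines[k].split()]
        if len(boxvals) not in (3, 9):
            raise TrajectoryParseError("box line needs 3 (or 9) values", k + 1)
        if len(boxvals) == 9 and any(v != 0 for v in boxvals[3:]):
            raise TrajectoryParseError("triclinic box not supported", k + 1)
        frames.append((time, np.array(boxvals[:3]), labels, np.array(pos), None))
        i = k + 1
    return frames


def _write_gro(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"frame t= {_FMT % traj.times[k]} ps\n")
            fh.write(f"{traj.n_particles}\n")
            for j, (sp, xyz) in enumerate(zip(traj.species, traj.positions[k])):
                resnum = (j + 1) % 100000
                fh.write("%5d%-5s%5s%5d %s %s %s\n"
                         % (resnum, sp[:5], sp[:5], resnum,
                            _FMT % xyz[0], _FMT % xyz[1], _FMT % xyz[2]))
            b = traj.boxes[k]
            fh.write(f"   {_FMT % b[0]} {_FMT % b[1]} {_FMT % b[2]}\n")


# ---------------------------------------------------------------------------
# LAMMPS dump text
# ---------------------------------------------------------------------------


def _read_lammps(path):
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    nlines = len(lines)
    while i < nlines:
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise TrajectoryParseError("expected ITEM: TIMESTEP", i + 1)
        step = int(lines[i + 1])
        if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise TrajectoryParseError("expected ITEM: NUMBER OF ATOMS", i + 3)
        n = int(lines[i + 3])
        if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
            raise TrajectoryParseError("expected ITEM: BOX BOUNDS", i + 5)
        if "xy" in lines[i + 4]:
            raise TrajectoryParseError("triclinic box not supported", i + 5)
        box = np.empty(3)
        for d in range(3):
            lo, hi = (float(x) for x in lines[i + 5 + d].split()[:2])
            box[d] = hi - lo
        hdr = lines[i + 8]
        if not hdr.startswith("ITEM: ATOMS"):
            raise TrajectoryParseError("expected ITEM: ATOMS", i + 9)
        cols = hdr.split()[2:]
        try:
            ci = {c: cols.index(c) for c in ("id", "type", "x", "y", "z")}
        except ValueError:
            raise TrajectoryParseError(
                "ATOMS columns must include id type x y z", i + 9)
        has_img = all(c in cols for c in ("ix", "iy", "iz"))
        recs = []
        for j in range(n):
            k = i + 9 + j
            if k >= nlines:
                raise TrajectoryParseError("truncated frame", nlines)
            parts = lines[k].split()
            if len(parts) < len(cols):
                raise TrajectoryParseError("short atom record", k + 1)
            try:
                rid = int(parts[ci["id"]])
                lab = parts[ci["type"]]
                xyz = [float(parts[ci["x"]]), float(parts[ci["y"]]),
                       float(parts[ci["z"]])]
                img = ([int(parts[cols.index("ix")]),
                        int(parts[cols.index("iy")]),
                        int(parts[cols.index("iz")])] if has_img else None)
            except ValueError:
                raise TrajectoryParseError("malformed atom record", k + 1)
            recs.append((rid, lab, xyz, img))
        recs.sort(key=lambda r: r[0])
        labels = [r[1] for r in recs]
        pos = np.array([r[2] for r in recs])
        imgs = np.array([r[3] for r in recs]) if has_img else None
        frames.append((float(step), box, labels, pos, imgs))
        i += 9 + n
    return frames


def _write_lammps(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            b = traj.boxes[k]
            fh.write("ITEM: TIMESTEP\n%d\n" % k)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % traj.n_particles)
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for d in range(3):
                fh.write("0 %s\n" % (_FMT % b[d]))
            if traj.image_flags is not None:
                fh.write("ITEM: ATOMS id type x y z ix iy iz\n")
                for j in range(traj.n_particles):
                    x, y, z = traj.positions[k, j]
                    ix, iy, iz = traj.image_flags[k, j]
                    fh.write("%d %s %s %s %s %d %d %d\n"
                             % (j + 1, traj.species[j], _FMT % x, _FMT % y,
                                _FMT % z, ix, iy, iz))
            else:
                fh.write("ITEM: ATOMS id type x y z\n")
                for j in range(traj.n_particles):
                    x, y, z = traj.positions[k, j]
                    fh.write("%d %s %s %s %s\n"
                             % (j + 1, traj.species[j], _FMT % x, _FMT % y,
                                _FMT % z))


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

_READERS = {"xyz_ext": _read_xyz, "gro_seq": _read_gro, "lammps_dump": _read_lammps}
_WRITERS = {"xyz_ext": _write_xyz, "gro_seq": _write_gro, "lammps_dump": _write_lammps}


def read_trajectory(path, format_name: str, topology, *, dt: float | None = None,
                    wrapped: bool = False) -> Trajectory:
    """Read a trajectory file in one of the supported text dialects.

    Parameters
    ----------
    topology : mapping
        File label (species name or LAMMPS type, as a string) -> role.
    dt : float, optional
        Frame spacing in ps.  Required for formats without timestamps
        (LAMMPS dumps); if the file carries times too, both must agree.
    wrapped : bool
        Whether coordinates in the file are folded into the box.
    """
    if format_name not in _READERS:
        raise ValueError(
            f"unsupported format {format_name!r}; supported: {SUPPORTED_FORMATS}")
    raw = _READERS[format_name](Path(path))
    if not raw:
        raise TrajectoryParseError("file contains no frames")

    n0 = len(raw[0][2])
    for idx, (_, _, labels, pos, _) in enumerate(raw):
        if len(labels) != n0:
            raise TrajectoryParseError(
                f"particle count mismatch: frame {idx} has {len(labels)}, "
                f"frame 0 has {n0}")

    labels0 = raw[0][2]
    roles = _resolve_topology(labels0, topology)

    file_times = [f[0] for f in raw]
    has_file_times = all(t is not None for t in file_times)
    if format_name == "lammps_dump":
        # step numbers, not times: dt is mandatory
        if dt is None:
            raise ValueError("lammps_dump carries step numbers, not times; "
                             "dt must be supplied")
        steps = np.array(file_times)
        if len(steps) > 2 and np.ptp(np.diff(steps)) > 0:
            raise TrajectoryParseError("non-uniform TIMESTEP spacing")
        times = np.arange(len(raw)) * dt
    elif has_file_times:
        times = np.array(file_times, dtype=float)
        if dt is not None and len(times) >= 2:
            file_dt = times[1] - times[0]
            if abs(file_dt - dt) > DT_UNIFORMITY_RTOL * max(abs(dt), 1e-30):
                raise ValueError(
                    f"configured dt = {dt} ps conflicts with file spacing "
                    f"{file_dt} ps")
    else:
        if dt is None:
            raise ValueError("file lacks timestamps; dt must be supplied")
        times = np.arange(len(raw)) * dt

    boxes = np.array([f[1] for f in raw])
    positions = np.array([f[3] for f in raw])
    imgs = None
    if all(f[4] is not None for f in raw):
        imgs = np.array([f[4] for f in raw])

    traj = Trajectory(times, boxes, positions, tuple(labels0), roles,
                      wrapped=wrapped, image_flags=imgs)
    if traj.n_frames >= 3 and not traj.has_uniform_dt():
        raise TrajectoryParseError("non-uniform frame spacing")
    logger.info("read %d frames x %d particles from %s (%s)",
                traj.n_frames, traj.n_particles, path, format_name)
    return traj


def write_trajectory(traj: Trajectory, path, format_name: str) -> None:
    """Write a trajectory in a supported dialect (>= 10 significant digits)."""
    if format_name not in _WRITERS:
        raise ValueError(
            f"unsupported format {format_name!r}; supported: {SUPPORTED_FORMATS}")
    _WRITERS[format_name](traj, Path(path))
    logger.info("wrote %d frames x %d particles to %s (%s)",
                traj.n_frames, traj.n_particles, path, format_name)


# ---------------------------------------------------------------------------
# Unwrapping
# ---------------------------------------------------------------------------


def unwrap_coordinates(traj: Trajectory) -> Trajectory:
    """Convert wrapped coordinates to continuous (unwrapped) ones.

    Successive per-particle displacements are taken as the minimum image of
    the wrapped step; frame-0 positions are kept.  When LAMMPS image flags
    are present they are used directly and cross-checked against the
    minimum-image reconstruction.  Already-unwrapped input is returned
    unchanged (idempotence).
    """
    if not traj.wrapped:
        return traj

    pos = traj.positions
    if traj.image_flags is not None:
        unwrapped = pos + traj.image_flags * traj.boxes[:, None, :]
        steps = np.diff(unwrapped, axis=0)
        raw = np.diff(pos, axis=0)
        boxes = traj.boxes[1:, None, :]
        mi = raw - boxes * np.round(raw / boxes)
        if steps.size and np.max(np.abs(steps - mi)) > 0.5 * float(traj.boxes.min()):
            raise ValueError("image flags disagree with minimum-image displacements; "
                             "inconsistent dump")
        return traj.with_positions(unwrapped, wrapped=False)

    if traj.n_frames == 1:
        return traj.with_positions(pos.copy(), wrapped=False)

    raw = np.diff(pos, axis=0)                      # (F-1, N, 3)
    boxes = traj.boxes[1:, None, :]
    mi = raw - boxes * np.round(raw / boxes)        # minimum-image steps
    half = 0.5 * boxes
    if np.any(np.abs(mi) >= half):
        raise ValueError(
            "ambiguous unwrapping: a minimum-image displacement reaches half "
            "the box edge; the trajectory is under-sampled")
    unwrapped = np.concatenate(
        [pos[:1], pos[:1] + np.cumsum(mi, axis=0)], axis=0)
    return traj.with_positions(unwrapped, wrapped=False)


def wrap_coordinates(traj: Trajectory) -> Trajectory:
    """Fold positions into [0, L) per dimension (for round-trip exercises)."""
    pos = np.mod(traj.positions, traj.boxes[:, None, :])
    return traj.with_positions(pos, wrapped=True)
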