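"""Point-group rotation operators and particle symmetry expansion.

The icosahedral pyruvate dehydrogenase E2 core contains 60 catalytic
domains arranged as 20 trimers on the vertices of a dodecahedron.
Sub-particle ("localized") reconstruction replicates each particle's
alignment under every proper rotation of the assembly's point group, so
that every trimer position superimposes onto a single reference trimer.
This module supplies the rotation operators, the table expansion, the
re-centering shifts, and stabilizer detection.

Conventions (fixed so results are bit-reproducible):

* Euler angles are ZYZ intrinsic ``(rot, tilt, psi)`` in degrees, with
  ``tilt`` in [0, 180].  The rotation matrix ``A(rot, tilt, psi) =
  Rz(psi) @ Ry(tilt) @ Rz(rot)`` maps map-frame coordinates into the
  particle image frame, matching the common single-particle STAR
  dialect.
* An expanded sub-particle composes the particle rotation with a group
  operator applied on the map side: ``A_sub = A_particle @ G``.
* Origin shifts are carried in Angstrom.  The re-centering shift
  translates the particle image so the chosen site lands at the image
  center: ``shift = prior_shift - (A @ v)[:2]``.
* The icosahedral group uses the 222 setting (2-fold axes along the
  coordinate axes); dodecahedral vertices sit at the normalized
  ``{(+-1,+-1,+-1), (0,+-1/phi,+-phi), (+-1/phi,+-phi,0),
  (+-phi,0,+-1/phi)}``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "RotationGroup",
    "generate_point_group",
    "euler_to_matrix",
    "matrix_to_euler",
    "expand_particles",
    "subparticle_shift",
    "stabilizer_order",
]

#: Columns a particle orientation table must carry.
PARTICLE_COLUMNS = ("particle_id", "core_id", "rot", "tilt", "psi", "origin_x", "origin_y")

_SYMBOL_RE = re.compile(r"^([CD])([1-9][0-9]*)$")

# matching tolerance when closing a group / deduplicating operators
_MATCH_TOL = 1e-6


def _rz(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _axis_rotation(axis, deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    return Rotation.from_rotvec(np.deg2rad(deg) * axis / np.linalg.norm(axis)).as_matrix()


@dataclass(frozen=True)
class RotationGroup:
    """A finite group of proper rotations identified by a Schoenflies symbol."""

    symbol: str
    operators: np.ndarray = field(repr=False)  # shape (order, 3, 3)

    def __post_init__(self):
        self.operators.setflags(write=False)

    @property
    def order(self) -> int:
        return len(self.operators)

    def __iter__(self):
        return iter(self.operators)

    def __len__(self) -> int:
        return self.order


def _close_under_products(generators: list[np.ndarray]) -> np.ndarray:
    """Return the closure of *generators* under composition.

    Operators are polished back onto SO(3) with an SVD projection after
    every product so float error cannot accumulate through long words.
    """
    ops: list[np.ndarray] = [np.eye(3)]
    frontier = list(generators)
    while frontier:
        new_frontier = []
        for g in frontier:
            for h in list(ops):
                for prod in (g @ h, h @ g):
                    u, _, vt = np.linalg.svd(prod)
                    cand = u @ vt
                    if not any(np.abs(cand - o).max() < _MATCH_TOL for o in ops):
                        ops.append(cand)
                        new_frontier.append(cand)
        frontier = new_frontier
        if len(ops) > 120:  # largest supported group is I with 60
            raise RuntimeError("group closure failed to terminate")
    return np.array(ops)


def _canonical_order(ops: np.ndarray) -> np.ndarray:
    """Identity first, then lexicographic on rounded entries (deterministic)."""
    keys = [tuple(np.round(o, 9).ravel()) for o in ops]
    idx = sorted(range(len(ops)), key=lambda i: (np.abs(ops[i] - np.eye(3)).max() > 1e-9, keys[i]))
    return ops[idx]


@lru_cache(maxsize=32)
def generate_point_group(symbol: str) -> RotationGroup:
    """Build the proper rotation group for a Schoenflies *symbol*.

    Supported symbols: ``Cn`` (order n), ``Dn`` (order 2n), ``T`` (12),
    ``O`` (24) and ``I`` (60).  The operator list is deterministic for a
    given symbol; the icosahedral group is produced in the 222 setting.
    Results are cached; the operator array is read-only.
    """
    if not isinstance(symbol, str):
        raise ValueError(f"symmetry symbol must be a string, got {symbol!r}")
    sym = symbol.strip()
    m = _SYMBOL_RE.match(sym)
    if m:
        family, n = m.group(1), int(m.group(2))
        cyclic = np.array([_rz(360.0 * k / n) for k in range(n)])
        if family == "C":
            return RotationGroup(sym, cyclic)
        flip = _axis_rotation((1.0, 0.0, 0.0), 180.0)
        ops = np.concatenate([cyclic, np.array([c @ flip for c in cyclic])])
        return RotationGroup(sym, ops)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    if sym == "T":
        gens = [_axis_rotation((0, 0, 1), 180.0), _axis_rotation((1, 1, 1), 120.0)]
    elif sym == "O":
        gens = [_axis_rotation((0, 0, 1), 90.0), _axis_rotation((1, 1, 1), 120.0)]
    elif sym == "I":
        # 5-fold chosen so the 3-fold axes land on the dodecahedral vertex
        # family {(+-1,+-1,+-1), (0,+-1/phi,+-phi), ...} of the 222 setting
        gens = [_axis_rotation((0, phi, 1), 72.0), _axis_rotation((1, 1, 1), 120.0)]
    else:
        raise ValueError(
            f"unknown symmetry symbol {symbol!r}; accepted: Cn (n>=1), Dn, T, O, I"
        )
    return RotationGroup(sym, _canonical_order(_close_under_products(gens)))


def euler_to_matrix(rot, tilt, psi) -> np.ndarray:
    """ZYZ intrinsic Euler angles (degrees) to map->image rotation matrices.

    Accepts scalars or equal-length arrays; returns shape (3, 3) or (n, 3, 3).
    """
    angles = np.stack(np.broadcast_arrays(np.asarray(psi, float), np.asarray(tilt, float), np.asarray(rot, float)), axis=-1)
    return Rotation.from_euler("ZYZ", angles, degrees=True).as_matrix()


def matrix_to_euler(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`euler_to_matrix`; returns ``(rot, tilt, psi)`` in degrees.

    ``tilt`` is returned in [0, 180]; at the gimbal degeneracy (tilt = 0 or
    180) the full in-plane angle is assigned to ``psi`` and ``rot`` is 0.
    """
    import warnings

    with warnings.catch_warnings():
        # at tilt = 0/180 scipy zeroes the redundant angle, which is
        # exactly the convention documented above
        warnings.filterwarnings("ignore", message="Gimbal lock")
        eul = Rotation.from_matrix(matrix).as_euler("ZYZ", degrees=True)
    eul = np.atleast_2d(eul)
    psi, tilt, rot = eul[:, 0], eul[:, 1], eul[:, 2]
    if np.ndim(matrix) == 2:
        return rot[0], tilt[0], psi[0]
    return rot, tilt, psi


def _validate_particles(particles: pd.DataFrame) -> None:
    missing = [c for c in PARTICLE_COLUMNS if c not in particles.columns]
    if missing:
        raise ValueError(f"particle table is missing columns: {missing}")
    if len(particles) == 0:
        raise ValueError("particle table is empty; nothing to expand")
    if particles["particle_id"].duplicated().any():
        dupes = particles.loc[particles["particle_id"].duplicated(), "particle_id"].tolist()
        raise ValueError(f"duplicate particle_id values: {dupes[:5]}")
    tilt = particles["tilt"].to_numpy(float)
    if ((tilt < 0) | (tilt > 180)).any():
        raise ValueError("tilt angles must lie in [0, 180] degrees")
    shifts = particles[["origin_x", "origin_y"]].to_numpy(float)
    if not np.isfinite(shifts).all():
        raise ValueError("origin shifts must be finite")


def _orbit_site_indices(group: RotationGroup, site: np.ndarray) -> np.ndarray:
    """Label each operator by which orbit point it sends *site* to.

    The orbit points are ordered deterministically (lexicographic on the
    rounded unit vectors), so labels are reproducible across runs.  For
    the icosahedral group and a dodecahedral vertex this yields 20 labels
    each shared by the 3 stabilizer-coset operators.
    """
    v = site / np.linalg.norm(site)
    images = np.einsum("gij,j->gi", group.operators, v)
    uniq: list[np.ndarray] = []
    labels = np.empty(len(images), dtype=int)
    for i, w in enumerate(images):
        for j, u in enumerate(uniq):
            if np.abs(w - u).max() < 1e-6:
                labels[i] = j
                break
        else:
            uniq.append(w)
            labels[i] = len(uniq) - 1
    order = sorted(range(len(uniq)), key=lambda j: tuple(np.round(uniq[j], 6)))
    relabel = {old: new for new, old in enumerate(order)}
    return np.array([relabel[l] for l in labels])


def expand_particles(
    particles: pd.DataFrame,
    group: RotationGroup,
    site: np.ndarray | None = None,
) -> pd.DataFrame:
    """Symmetry-expand a particle table: one sub-particle per (row, operator).

    Each sub-particle's orientation is the parent orientation composed
    with a map-frame group operator, so every symmetry-equivalent site of
    the assembly is aligned onto the same reference position.  When
    *site* (a map-frame vector in Angstrom, or a unit direction) is
    given, origin shifts are re-centered onto that site and each row is
    labelled with the physical site it images (``site_index``).

    Returns a table of ``len(particles) * group.order`` rows; grouping on
    ``parent_particle_id`` and taking ``operator_index == 0`` recovers
    the parent rows exactly.
    """
    _validate_particles(particles)
    n, g = len(particles), group.order
    r_part = euler_to_matrix(
        particles["rot"].to_numpy(float),
        particles["tilt"].to_numpy(float),
        particles["psi"].to_numpy(float),
    )
    # composed[p, k] = R_p @ G_k
    composed = np.einsum("pij,kjl->pkil", r_part, group.operators).reshape(n * g, 3, 3)
    rot, tilt, psi = matrix_to_euler(composed)

    ox = np.repeat(particles["origin_x"].to_numpy(float), g)
    oy = np.repeat(particles["origin_y"].to_numpy(float), g)
    if site is not None:
        v = np.asarray(site, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError("site vector must be finite")
        proj = np.einsum("sij,j->si", composed, v)
        ox = ox - proj[:, 0]
        oy = oy - proj[:, 1]
        site_index = np.tile(_orbit_site_indices(group, v), n)
    else:
        site_index = np.full(n * g, -1, dtype=int)

    out = pd.DataFrame(
        {
            "subparticle_id": np.arange(n * g),
            "parent_particle_id": np.repeat(particles["particle_id"].to_numpy(), g),
            "core_id": np.repeat(particles["core_id"].to_numpy(), g),
            "operator_index": np.tile(np.arange(g), n),
            "rot": rot,
            "tilt": tilt,
            "psi": psi,
            "origin_x": ox,
            "origin_y": oy,
            "site_index": site_index,
        }
    )
    return out


def subparticle_shift(rot, tilt, psi, origin_x, origin_y, site) -> tuple[float, float]:
    """In-plane shift (Angstrom) that re-centers the image on *site*.

    The site vector lives in the map frame; it is rotated into the image
    frame and its in-plane components are subtracted from the prior
    origin shift, so applying the returned shift translates the particle
    image until the site projects at the image center.
    """
    v = np.asarray(site, dtype=float)
    if v.shape != (3,) or not np.isfinite(v).all():
        raise ValueError("site must be a finite 3-vector")
    r = euler_to_matrix(rot, tilt, psi)
    proj = r @ v
    return float(origin_x - proj[0]), float(origin_y - proj[1])


def stabilizer_order(group: RotationGroup, axis, tol_rad: float = 1e-6) -> int:
    """Number of group operators fixing *axis* (angular tolerance in radians).

    For a 3-fold site of the icosahedral assembly this is 3 — the reason
    expanded detections per physical trimer come in multiples of three.
    """
    a = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(a)
    if norm == 0 or not np.isfinite(norm):
        raise ValueError("axis must be a non-zero finite vector")
    a = a / norm
    images = np.einsum("gij,j->gi", group.operators, a)
    cosang = np.clip(images @ a, -1.0, 1.0)
    return int(np.count_nonzero(np.arccos(cosang) < tol_rad))
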