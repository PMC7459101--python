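"""Nuclear geometry: ellipsoid models, radial ratios and the distance index.

The central normalization of the radial analysis divides the nuclear volume
into ``n_shells`` concentric, *equal-volume* ("isovolumetric") spheroidal
shells sharing the nuclear centre. A FISH signal is assigned to a shell from
its radial ratio rho — the distance from the nuclear centre divided by the
boundary radius along the ray through the signal — which maps a uniform
spatial null to a flat shell occupancy. The continuous form of this index is
rho**3 ("volume mode"), running from 0.0 at the nuclear centre to 1.0 at the
border; the raw ratio rho is available as "linear mode".

All coordinates are micrometres in the lab frame. Voxel masks use the
voxel-centre convention with array index order (z, y, x).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InvalidInputError, OutOfNucleusError, PairingError

logger = logging.getLogger(__name__)

#: default number of isovolumetric shells used for the distance index
DEFAULT_N_SHELLS = 10_000

#: default out-of-boundary clamping tolerance on the radial ratio
DEFAULT_RHO_TOL = 0.05

IndexMode = Literal["volume", "linear"]


@dataclass(frozen=True)
class NucleusModel:
    """Parametric ellipsoid model of one nucleus.

    Parameters
    ----------
    nucleus_id : str
        Identifier linking spots to this nucleus.
    center : (3,) array
        Centre in µm, lab frame.
    semi_axes : (3,) array
        Semi-axes (a, b, c) in µm, sorted a >= b >= c, all positive.
    orientation : (3, 3) array
        Rotation matrix mapping principal-frame vectors into the lab frame
        (columns are the principal axes). Orthonormal, det +1.
    volume : float
        Nuclear volume in µm³. For ``source="parametric"`` this is exactly
        (4/3)·pi·a·b·c; for masks it is the measured voxel volume.
    feret : float
        Maximum caliper diameter in µm (2·a for a parametric model).
    source : {"parametric", "mask_fit"}
    group : str, optional
        Population label (e.g. ``"Mb"`` or ``"Mt"``).
    """

    nucleus_id: str
    center: np.ndarray
    semi_axes: np.ndarray
    orientation: np.ndarray
    volume: float
    feret: float
    source: Literal["parametric", "mask_fit"] = "parametric"
    group: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        axes = np.asarray(self.semi_axes, dtype=float)
        rot = np.asarray(self.orientation, dtype=float)
        object.__setattr__(self, "semi_axes", axes)
        object.__setattr__(self, "orientation", rot)
        if axes.shape != (3,) or not np.all(axes > 0):
            raise InvalidInputError(
                f"nucleus {self.nucleus_id}: semi-axes must be 3 positive values, got {axes}"
            )
        if not np.all(np.diff(axes) <= 0):
            raise InvalidInputError(
                f"nucleus {self.nucleus_id}: semi-axes must be sorted descending, got {axes}"
            )
        if rot.shape != (3, 3) or not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9):
            raise InvalidInputError(
                f"nucleus {self.nucleus_id}: orientation must be orthonormal"
            )
        if not math.isclose(float(np.linalg.det(rot)), 1.0, abs_tol=1e-9):
            raise InvalidInputError(
                f"nucleus {self.nucleus_id}: orientation must be a proper rotation (det +1)"
            )

    @classmethod
    def parametric(
        cls,
        nucleus_id: str,
        center,
        semi_axes,
        orientation=None,
        group: str | None = None,
    ) -> "NucleusModel":
        """Build a parametric model; volume and Feret follow from the axes."""
        axes = np.sort(np.asarray(semi_axes, dtype=float))[::-1]
        rot = np.eye(3) if orientation is None else np.asarray(orientation, float)
        a, b, c = axes
        return cls(
            nucleus_id=nucleus_id,
            center=np.asarray(center, dtype=float),
            semi_axes=axes,
            orientation=rot,
            volume=4.0 / 3.0 * math.pi * a * b * c,
            feret=2.0 * a,
            source="parametric",
            group=group,
        )


@dataclass(frozen=True)
class VoxelMask:
    """Binary 3D nucleus mask with physical voxel spacing.

    ``array`` is indexed (z, y, x); ``spacing`` is (dx, dy, dz) in µm and
    voxel centres define physical positions.
    """

    array: np.ndarray
    spacing: tuple[float, float, float] = (0.13, 0.13, 0.2)

    def __post_init__(self) -> None:
        arr = np.asarray(self.array, dtype=bool)
        object.__setattr__(self, "array", arr)
        if arr.ndim != 3:
            raise InvalidInputError(f"mask must be 3D, got {arr.ndim}D")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidInputError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def n_voxels(self) -> int:
        return int(self.array.sum())

    def voxel_centers(self) -> np.ndarray:
        """Physical (x, y, z) µm coordinates of all true voxel centres."""
        zz, yy, xx = np.nonzero(self.array)
        dx, dy, dz = self.spacing
        return np.column_stack([xx * dx, yy * dy, zz * dz])


@dataclass(frozen=True)
class Spot:
    """One FISH signal: nucleus membership, probe identity, 3D position (µm)."""

    spot_id: str
    nucleus_id: str
    probe_id: str
    position: np.ndarray
    signal_volume: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise InvalidInputError(
                f"spot {self.spot_id}: position must be a finite 3-vector, got {pos}"
            )


@dataclass(frozen=True)
class RadialIndexResult:
    """Radial position of one spot after shell normalization."""

    spot_id: str
    radial_ratio: float
    shell_index: int
    normalized_distance_index: float
    n_shells: int = DEFAULT_N_SHELLS
    mode: IndexMode = "volume"


# ---------------------------------------------------------------------------
# mask fitting


def fit_ellipsoid_from_mask(
    mask: VoxelMask, nucleus_id: str = "nucleus", group: str | None = None
) -> NucleusModel:
    """Fit an ellipsoid to a binary mask by matching second-order moments.

    A solid ellipsoid with semi-axis a has second central moment a²/5 along
    that axis, so the fitted semi-axes are sqrt(5·eigenvalues) of the voxel
    covariance. The reported volume is the measured mask volume
    (voxel count × voxel volume); the Feret diameter comes from the fitted
    model (2·a).

    Raises
    ------
    InvalidInputError
        If the mask holds fewer than 30 voxels (the moment fit is unstable
        below that).
    """
    n = mask.n_voxels
    if n < 30:
        raise InvalidInputError(
            f"nucleus {nucleus_id}: mask has {n} voxels; need >= 30 for a moment fit"
        )
    pts = mask.voxel_centers()
    center = pts.mean(axis=0)
    cov = np.cov(pts.T, bias=True)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.any(evals <= 0):
        raise InvalidInputError(f"nucleus {nucleus_id}: degenerate mask (flat in one axis)")
    semi_axes = np.sqrt(5.0 * evals)
    if np.linalg.det(evecs) < 0:
        evecs = evecs.copy()
        evecs[:, 2] = -evecs[:, 2]
    return NucleusModel(
        nucleus_id=nucleus_id,
        center=center,
        semi_axes=semi_axes,
        orientation=evecs,
        volume=n * mask.voxel_volume,
        feret=2.0 * float(semi_axes[0]),
        source="mask_fit",
        group=group,
    )


# ---------------------------------------------------------------------------
# scalar morphometry


def flattening(volume: float, cross_section_diameter: float) -> float:
    """Flattening from nuclear volume and equatorial cross-section diameter.

    Models the nucleus as an oblate spheroid with equatorial radius
    a = diameter/2; the polar radius consistent with the volume is
    c = 3·V / (4·pi·a²). Returns f = (c - a)/a: 0 for a sphere, negative for
    flattened/elongated nuclei (the more negative, the less spheroidal).
    The sign convention follows the ordering of published myoblast/myotube
    values and is a documented convention, not uniquely determined.
    """
    if volume <= 0 or cross_section_diameter <= 0:
        raise InvalidInputError(
            f"volume and diameter must be positive, got {volume}, {cross_section_diameter}"
        )
    a = cross_section_diameter / 2.0
    c = 3.0 * volume / (4.0 * math.pi * a * a)
    return (c - a) / a


def radius_along_ray(nucleus: NucleusModel, direction: np.ndarray) -> float:
    """Distance from the centre to the ellipsoid surface along a unit ray.

    In the principal frame with unit direction u the boundary radius is
    1 / sqrt(sum(u_i² / a_i²)).
    """
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise InvalidInputError("direction must be a non-zero vector")
    if abs(norm - 1.0) > 1e-9:
        raise InvalidInputError(f"direction must be unit length, |d| = {norm}")
    u = nucleus.orientation.T @ d  # lab -> principal
    return float(1.0 / math.sqrt(np.sum((u / nucleus.semi_axes) ** 2)))


def radial_ratio(
    nucleus: NucleusModel, spot: Spot, tol: float = DEFAULT_RHO_TOL
) -> float:
    """Radial ratio rho of a spot: centre distance / boundary radius on its ray.

    Spots marginally outside the fitted boundary (1 < rho <= 1 + tol) are
    clamped to 1.0 with a warning — fitted ellipsoids never contain every
    segmented spot exactly. Beyond the tolerance an
    :class:`~nucorg.errors.OutOfNucleusError` is raised.
    """
    if spot.nucleus_id != nucleus.nucleus_id:
        raise PairingError(
            f"spot {spot.spot_id} belongs to nucleus {spot.nucleus_id}, "
            f"not {nucleus.nucleus_id}"
        )
    offset = spot.position - nucleus.center
    dist = float(np.linalg.norm(offset))
    if dist == 0.0:
        return 0.0
    r = radius_along_ray(nucleus, offset / dist)
    rho = dist / r
    if rho > 1.0 + tol:
        raise OutOfNucleusError(
            f"spot {spot.spot_id} lies at rho={rho:.4f} > 1+{tol} outside nucleus "
            f"{nucleus.nucleus_id} (segmentation/fit mismatch)"
        )
    if rho > 1.0:
        logger.warning(
            "spot %s at rho=%.4f clamped to nuclear boundary of %s",
            spot.spot_id,
            rho,
            nucleus.nucleus_id,
        )
        rho = 1.0
    return rho


def normalized_distance_index(
    rho: float,
    spot_id: str = "",
    n_shells: int = DEFAULT_N_SHELLS,
    mode: IndexMode = "volume",
) -> RadialIndexResult:
    """Map a radial ratio to its shell and continuous distance index.

    In volume mode shell k is the smallest k with rho³ <= k/N — the
    equal-volume shell the signal falls in — and the continuous index is
    rho³, so a population uniform in nuclear volume is flat both per shell
    and on the index. Linear mode keeps the raw ratio with equal-width
    shells in rho.
    """
    if not 0.0 <= rho <= 1.0:
        raise InvalidInputError(f"radial ratio must be in [0, 1], got {rho}")
    if n_shells < 1:
        raise InvalidInputError(f"n_shells must be >= 1, got {n_shells}")
    if mode not in ("volume", "linear"):
        raise InvalidInputError(f"unknown index mode {mode!r}")
    index = rho**3 if mode == "volume" else rho
    # small backoff so an index sitting exactly on a shell boundary (up to
    # fp rounding) lands in that shell, per "smallest k with index <= k/N"
    shell = max(1, math.ceil(index * n_shells - 1e-9))
    shell = min(shell, n_shells)
    return RadialIndexResult(
        spot_id=spot_id,
        radial_ratio=float(rho),
        shell_index=shell,
        normalized_distance_index=float(index),
        n_shells=n_shells,
        mode=mode,
    )


def spot_distance_index(
    nucleus: NucleusModel,
    spot: Spot,
    n_shells: int = DEFAULT_N_SHELLS,
    mode: IndexMode = "volume",
    tol: float = DEFAULT_RHO_TOL,
) -> RadialIndexResult:
    """Convenience composition: radial ratio then shell normalization."""
    rho = radial_ratio(nucleus, spot, tol=tol)
    return normalized_distance_index(rho, spot_id=spot.spot_id, n_shells=n_shells, mode=mode)


def feret_diameter(obj: NucleusModel | VoxelMask) -> float:
    """Maximum caliper (Feret) diameter in µm.

    Parametric models: 2·max semi-axis. Masks: the maximum pairwise extent
    of surface voxel centres, computed over the convex hull so only O(hull²)
    pairs are examined.
    """
    if isinstance(obj, NucleusModel):
        return 2.0 * float(obj.semi_axes[0])
    if not isinstance(obj, VoxelMask):
        raise InvalidInputError(f"expected NucleusModel or VoxelMask, got {type(obj)!r}")
    if obj.n_voxels == 0:
        raise InvalidInputError("cannot compute Feret diameter of an empty mask")
    pts = obj.voxel_centers()
    if len(pts) < 4:
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        return float(d.max())
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:  # coplanar / collinear voxel sets
        verts = pts
    d = np.linalg.norm(verts[:, None, :] - verts[None, :, :], axis=-1)
    return float(d.max())
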