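"""Virtual bipolar mapping catheters: designs, electrode patches, placement.

Three built-in designs mirror commercial mapping catheters:

* Thermocool — cylindrical electrodes, 3.5 mm tip, 2 mm spacing;
* Pentaray — cylindrical electrodes, 1 mm tip, 2 mm spacing (one bipole of
  the multi-spline catheter);
* Orion — flat electrodes of 0.4 mm^2 area, 2.5 mm spacing.

Electrode surfaces are subdivided into small patches (~0.07 mm^2); the
extracellular potential is evaluated at every patch and averaged per
electrode, which is what makes electrode size/shape matter: the far side of
a cylindrical electrode is lifted off the tissue and dilutes the average,
while a flat electrode face sits uniformly close.

Pose convention (tip touching the tissue at the contact point):

* contact angle CA — angle between the catheter axis and the tissue surface
  (0 deg = shaft lying along the surface, 90 deg = perpendicular tip contact);
* catheter orientation CO — angle between the tangential projection of the
  axis and the local activation-wavefront direction.

Inter-electrode spacing is interpreted edge-to-edge. The nearest patch is
kept a small clearance above the surface so the 1/r source kernel stays
bounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, PlacementError
from .mesh import TissueModel

CONTACT_CLEARANCE_MM = 0.05
DEFAULT_MAX_PATCH_AREA = 0.07  # mm^2


@dataclass(frozen=True)
class CatheterDesign:
    """Two-electrode bipolar catheter geometry (dimensions in mm / mm^2)."""

    name: str
    electrode_shape: str            # "cylindrical" | "flat"
    distal_length: float = 0.0      # cylindrical: tip electrode length
    flat_area: float = 0.0          # flat: per-electrode face area
    proximal_length: float = 0.0    # cylindrical: ring electrode length
    shaft_diameter: float = 1.0
    spacing: float = 2.0            # edge-to-edge inter-electrode spacing

    def __post_init__(self):
        if self.electrode_shape not in ("cylindrical", "flat"):
            raise ConfigurationError("electrode_shape must be cylindrical|flat")
        if self.spacing <= 0 or self.shaft_diameter <= 0:
            raise ConfigurationError("catheter dimensions must be positive")
        if self.electrode_shape == "cylindrical" and (
                self.distal_length <= 0 or self.proximal_length <= 0):
            raise ConfigurationError("cylindrical electrodes need positive lengths")
        if self.electrode_shape == "flat" and self.flat_area <= 0:
            raise ConfigurationError("flat electrodes need a positive area")


@dataclass
class CatheterPose:
    """Placement of a catheter against the tissue surface."""

    contact_point: np.ndarray   # (3,) mm, on the mesh surface
    co: float                   # catheter orientation vs wavefront, deg
    ca: float                   # contact angle vs surface, deg

    def __post_init__(self):
        if not (0.0 <= self.co <= 90.0 and 0.0 <= self.ca <= 90.0):
            raise ConfigurationError("co and ca must lie in [0, 90] degrees")
        self.contact_point = np.asarray(self.contact_point, dtype=float)


@dataclass
class ElectrodePatches:
    """Patch decomposition of both electrodes (catheter-local or world frame).

    Local frame: the catheter axis is +x with the distal tip at the origin;
    -z is the side facing the tissue at CA = 0.
    """

    centers: np.ndarray        # (m, 3)
    areas: np.ndarray          # (m,)
    electrode: np.ndarray      # (m,) 0 = distal, 1 = proximal

    @property
    def n_patches(self) -> int:
        return self.centers.shape[0]

    def electrode_area(self, which: int) -> float:
        return float(self.areas[self.electrode == which].sum())


def bipole_half_extent(design: CatheterDesign) -> float:
    """Half the tip-to-proximal-end footprint length along the shaft (mm)."""
    if design.electrode_shape == "cylindrical":
        total = design.distal_length + design.spacing + design.proximal_length
    else:
        side = np.sqrt(design.flat_area)
        total = side + design.spacing + side
    return total / 2.0


def builtin_designs() -> tuple:
    """The three built-in catheter designs (Thermocool, Pentaray, Orion)."""
    thermocool = CatheterDesign(
        name="Thermocool", electrode_shape="cylindrical",
        distal_length=3.5, proximal_length=1.0,
        shaft_diameter=2.3, spacing=2.0)
    pentaray = CatheterDesign(
        name="Pentaray", electrode_shape="cylindrical",
        distal_length=1.0, proximal_length=1.0,
        shaft_diameter=1.0, spacing=2.0)
    orion = CatheterDesign(
        name="Orion", electrode_shape="flat",
        flat_area=0.4, shaft_diameter=1.0, spacing=2.5)
    return thermocool, pentaray, orion


def _cylinder_patches(x0: float, length: float, radius: float,
                      max_area: float, with_tip_dome: bool):
    """Patches of a cylindrical electrode along +x starting at x0.

    With ``with_tip_dome`` the front of the electrode is a hemispherical
    dome (ablation-tip shape): the dome spans x in [x0, x0 + radius] and the
    lateral surface continues to x0 + length, so the total surface area is
    exactly pi * diameter * length. Without it, only the lateral surface is
    tessellated (ring electrode).
    """
    centers, areas = [], []
    side = np.sqrt(max_area)
    if with_tip_dome:
        if length <= radius:
            raise ConfigurationError("electrode shorter than its tip dome")
        n_th = max(2, int(np.ceil((np.pi / 2) * radius / side)))
        dth = (np.pi / 2) / n_th
        for k in range(n_th):
            th0, th1 = k * dth, (k + 1) * dth
            th = 0.5 * (th0 + th1)
            band_area = 2 * np.pi * radius ** 2 * (np.cos(th0) - np.cos(th1))
            rho = radius * np.sin(th)
            n_s = max(3, int(np.ceil(band_area / max_area)))
            ds = 2 * np.pi / n_s
            for s in range(n_s):
                phi = (s + 0.5) * ds
                centers.append([x0 + radius * (1.0 - np.cos(th)),
                                rho * np.cos(phi), rho * np.sin(phi)])
                areas.append(band_area / n_s)
        lat_x0, lat_len = x0 + radius, length - radius
    else:
        lat_x0, lat_len = x0, length
    lat_area = 2 * np.pi * radius * lat_len
    n_ax = max(1, int(np.ceil(lat_len / side)))
    # circumferential count chosen from the area budget so that the patch
    # count scales (at least) inversely with max_area
    n_circ = max(3, int(np.ceil(lat_area / (n_ax * max_area))))
    dx = lat_len / n_ax
    dphi = 2 * np.pi / n_circ
    for x in lat_x0 + (np.arange(n_ax) + 0.5) * dx:
        for phi in (np.arange(n_circ) + 0.5) * dphi:
            centers.append([x, radius * np.cos(phi), radius * np.sin(phi)])
            areas.append(radius * dphi * dx)
    return centers, areas


def _flat_patches(x0: float, side_len: float, z_face: float, max_area: float):
    """Square flat electrode face at height z_face, normal -z.

    The patch count is chosen from the area budget ceil(area / max_area)
    and factored into a near-square grid, so halving max_area at least
    doubles the count.
    """
    centers, areas = [], []
    n_target = max(1, int(np.ceil(side_len ** 2 / max_area)))
    rows = max(1, int(np.floor(np.sqrt(n_target))))
    cols = int(np.ceil(n_target / rows))
    dx = side_len / cols
    dy = side_len / rows
    for i in range(cols):
        for j in range(rows):
            centers.append([x0 + (i + 0.5) * dx,
                            (j + 0.5) * dy - side_len / 2.0, z_face])
            areas.append(dx * dy)
    return centers, areas


def subdivide_electrodes(design: CatheterDesign,
                         max_patch_area: float = DEFAULT_MAX_PATCH_AREA
                         ) -> ElectrodePatches:
    """Patch decomposition of both electrodes in the catheter-local frame."""
    if max_patch_area > 0.1:
        raise ConfigurationError("max_patch_area must be <= 0.1 mm^2")
    centers, areas, electrode = [], [], []
    if design.electrode_shape == "cylindrical":
        r = design.shaft_diameter / 2.0
        c, a = _cylinder_patches(0.0, design.distal_length, r,
                                 max_patch_area, with_tip_dome=True)
        centers += c; areas += a; electrode += [0] * len(a)
        x_prox = design.distal_length + design.spacing
        c, a = _cylinder_patches(x_prox, design.proximal_length, r,
                                 max_patch_area, with_tip_dome=False)
        centers += c; areas += a; electrode += [1] * len(a)
    else:
        side = np.sqrt(design.flat_area)
        z_face = -design.shaft_diameter / 2.0
        c, a = _flat_patches(0.0, side, z_face, max_patch_area)
        centers += c; areas += a; electrode += [0] * len(a)
        c, a = _flat_patches(side + design.spacing, side, z_face, max_patch_area)
        centers += c; areas += a; electrode += [1] * len(a)
    return ElectrodePatches(centers=np.array(centers, dtype=float),
                            areas=np.array(areas, dtype=float),
                            electrode=np.array(electrode, dtype=np.int8))


def place(design: CatheterDesign, pose: CatheterPose, tissue: TissueModel,
          wave_direction, *,
          max_patch_area: float = DEFAULT_MAX_PATCH_AREA,
          clearance: float = CONTACT_CLEARANCE_MM,
          patches: ElectrodePatches | None = None) -> ElectrodePatches:
    """Rigidly place the subdivided catheter against the tissue surface.

    The catheter axis makes angle CA with the local tangent plane, its
    tangential projection makes angle CO with ``wave_direction`` (a unit
    tangent at the contact point), and the whole body is lifted along the
    surface normal until its closest patch sits ``clearance`` above the
    surface. Precomputed local-frame ``patches`` may be passed to avoid
    re-subdivision.
    """
    if patches is None:
        patches = subdivide_electrodes(design, max_patch_area)
    node = tissue.nearest_node(pose.contact_point)
    normal = tissue.node_normals()[node]
    wave = np.asarray(wave_direction, dtype=float)
    wave = wave - np.dot(wave, normal) * normal
    if np.linalg.norm(wave) < 1e-9:
        raise PlacementError("wave direction is not tangent to the surface")
    wave /= np.linalg.norm(wave)

    co = np.deg2rad(pose.co)
    ca = np.deg2rad(pose.ca)
    side = np.cross(normal, wave)
    tangential = np.cos(co) * wave + np.sin(co) * side
    axis = np.cos(ca) * tangential + np.sin(ca) * normal

    up = normal - np.dot(normal, axis) * axis
    if np.linalg.norm(up) < 1e-9:     # axis along the normal (CA = 90)
        up = wave - np.dot(wave, axis) * axis
    up /= np.linalg.norm(up)
    ey = np.cross(up, axis)
    rot = np.column_stack([axis, ey, up])   # local x, y, z -> world

    world = pose.contact_point + patches.centers @ rot.T
    heights = (world - pose.contact_point) @ normal
    world = world + (clearance - heights.min()) * normal

    heights = (world - pose.contact_point) @ normal
    if heights.min() < clearance - 1e-9:
        raise PlacementError("catheter patches penetrate the tissue surface")
    return ElectrodePatches(centers=world, areas=patches.areas.copy(),
                            electrode=patches.electrode.copy())


def wavefront_direction(tissue: TissueModel, activation_times: np.ndarray,
                        node: int, radius_mm: float = 2.0) -> np.ndarray:
    """Local propagation direction from the activation-time gradient.

    Least-squares plane fit of activation times over the nodes within
    ``radius_mm`` of the given node; the unit gradient (projected onto the
    surface) is the direction the wave travels.
    """
    p = tissue.nodes
    d = np.linalg.norm(p - p[node], axis=1)
    sel = np.flatnonzero((d <= radius_mm) & np.isfinite(activation_times))
    if sel.size < 3:
        raise ConfigurationError("too few activated neighbours for a gradient")
    A = p[sel] - p[node]
    b = activation_times[sel] - np.nanmean(activation_times[sel])
    g, *_ = np.linalg.lstsq(A, b, rcond=None)
    normal = tissue.node_normals()[node]
    g = g - np.dot(g, normal) * normal
    ng = np.linalg.norm(g)
    if ng < 1e-12:
        raise ConfigurationError("vanishing activation-time gradient")
    return g / ng
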