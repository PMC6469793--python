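"""Synthetic geometry, scars, fibrosis, and stand-in clinical voltage maps.

Everything downstream of this module runs on data generated here: rectangular
or cylindrically curved triangulated sheets, circular non-conductive scars,
the cubic voltage-to-fibrosis-probability relation with stochastic node
assignment, and smooth random bipolar-voltage fields that play the role of a
clinically acquired map (the generator emulates only the property that
matters downstream: a spatially smooth positive voltage field in the
physiological 0.1-6 mV range).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .mesh import TissueModel, lumped_areas

SCAR_BOUNDARY_MARGIN_MM = 5.0


@dataclass
class ScarSpec:
    """Circular non-conductive region: center (sheet coordinates, mm) + diameter."""

    center: tuple
    diameter: float

    def __post_init__(self):
        if self.diameter < 0:
            raise ConfigurationError("scar diameter must be >= 0")


@dataclass
class SyntheticVoltageMap:
    """Per-node bipolar voltage field standing in for a clinical map."""

    values: np.ndarray          # (n,) mV
    correlation_length_mm: float
    range_mv: tuple
    seed: int


def make_sheet(width: float, height: float, spacing: float = 0.25,
               curvature: float | None = None, **tissue_kwargs) -> TissueModel:
    """Triangulated sheet of the given dimensions.

    ``curvature`` (a radius in mm) bends the sheet into a cylindrical patch
    about the y axis, preserving arc-length spacing, so that non-zero
    contact-angle geometry can be exercised against a genuinely curved
    surface. Node order is row-major over the structured (ny, nx) grid.
    """
    if width <= 0 or height <= 0 or spacing <= 0:
        raise ConfigurationError("sheet dimensions and spacing must be positive")
    if spacing > 0.5:
        raise ConfigurationError("node spacing must be <= 0.5 mm")
    nx = int(round(width / spacing)) + 1
    ny = int(round(height / spacing)) + 1
    if nx < 2 or ny < 2:
        raise ConfigurationError("degenerate sheet dimensions")
    x = np.arange(nx) * spacing
    y = np.arange(ny) * spacing
    xx, yy = np.meshgrid(x, y)
    if curvature is None:
        nodes = np.column_stack([xx.ravel(), yy.ravel(),
                                 np.zeros(nx * ny)])
    else:
        r = float(curvature)
        if r <= 0:
            raise ConfigurationError("curvature radius must be positive")
        theta = (xx.ravel() - width / 2.0) / r
        nodes = np.column_stack([
            width / 2.0 + r * np.sin(theta),
            yy.ravel(),
            r * (np.cos(theta) - 1.0),
        ])

    # two right triangles per grid cell
    ii, jj = np.meshgrid(np.arange(ny - 1), np.arange(nx - 1), indexing="ij")
    v00 = (ii * nx + jj).ravel()
    v01 = v00 + 1
    v10 = v00 + nx
    v11 = v10 + 1
    tris = np.concatenate([
        np.column_stack([v00, v01, v11]),
        np.column_stack([v00, v11, v10]),
    ]).astype(np.int64)

    area = lumped_areas(nodes, tris)
    return TissueModel(nodes=nodes, triangles=tris, node_area=area,
                       grid_shape=(ny, nx), spacing=spacing, **tissue_kwargs)


def sheet_coordinates(tissue: TissueModel) -> np.ndarray:
    """Flat (u, v) sheet-parameter coordinates of every node.

    For flat sheets these are x, y; for cylindrical patches u is arc length,
    recovered from the grid structure.
    """
    if tissue.grid_shape is not None and tissue.spacing is not None:
        ny, nx = tissue.grid_shape
        u = np.tile(np.arange(nx) * tissue.spacing, ny)
        v = np.repeat(np.arange(ny) * tissue.spacing, nx)
        return np.column_stack([u, v])
    return tissue.nodes[:, :2].copy()


def apply_scar(tissue: TissueModel, spec: ScarSpec) -> TissueModel:
    """Flag nodes inside the scar disc as non-conductive (strict < radius)."""
    if spec.diameter == 0:
        return tissue.with_masks(scar_mask=np.zeros(tissue.n_nodes, dtype=bool))
    uv = sheet_coordinates(tissue)
    lo = uv.min(axis=0)
    hi = uv.max(axis=0)
    c = np.asarray(spec.center, dtype=float)
    r = spec.diameter / 2.0
    if np.any(c - r < lo + SCAR_BOUNDARY_MARGIN_MM) or \
            np.any(c + r > hi - SCAR_BOUNDARY_MARGIN_MM):
        raise ConfigurationError(
            f"scar (center {tuple(c)}, diameter {spec.diameter}) closer than "
            f"{SCAR_BOUNDARY_MARGIN_MM} mm to the sheet boundary")
    dist = np.linalg.norm(uv - c, axis=1)
    mask = dist < r
    return tissue.with_masks(scar_mask=mask)


def fibrosis_probability(x, clamp: bool = True):
    """Fibrosis probability (%) as a cubic in the local bipolar voltage (mV).

    Y = -40.0 X^3 + 155 X^2 - 206 X + 99.8, interpreted on the percent
    scale (its value at X=0 is 99.8). Outside [0, 100] the cubic is clamped
    when ``clamp`` is set, since probabilities must be bounded.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("bipolar voltage must be >= 0 mV")
    y = -40.0 * x ** 3 + 155.0 * x ** 2 - 206.0 * x + 99.8
    if clamp:
        y = np.clip(y, 0.0, 100.0)
    if y.ndim == 0:
        return float(y)
    return y


def assign_fibrosis(tissue: TissueModel, vmap: SyntheticVoltageMap,
                    seed: int) -> TissueModel:
    """Independent per-node Bernoulli fibrosis draws from the voltage map.

    The per-node probability is ``fibrosis_probability(x)/100``; scar nodes
    are never marked fibrotic. Identical seeds give identical masks.
    """
    x = np.asarray(vmap.values, dtype=float)
    if x.shape[0] != tissue.n_nodes:
        raise ConfigurationError("voltage map not defined on every node")
    p = fibrosis_probability(x) / 100.0
    rng = np.random.default_rng(seed)
    mask = rng.random(tissue.n_nodes) < p
    mask &= ~tissue.scar_mask
    return tissue.with_masks(fibrosis_mask=mask)


def make_synthetic_clinical_map(tissue: TissueModel,
                                range_mv: tuple = (0.1, 6.0),
                                correlation_length_mm: float = 8.0,
                                seed: int = 0) -> SyntheticVoltageMap:
    """Smooth positive random voltage field over the mesh.

    Gaussian-smoothed uniform noise rescaled to ``range_mv``. On structured
    sheets the smoothing runs on the grid; on unstructured meshes it is a
    graph-diffusion equivalent. Reproducible under ``seed``.
    """
    lo, hi = float(range_mv[0]), float(range_mv[1])
    if not (0 < lo < hi <= 20.0):
        raise ConfigurationError("voltage range must satisfy 0 < lo < hi <= 20 mV")
    rng = np.random.default_rng(seed)
    noise = rng.random(tissue.n_nodes)
    if tissue.grid_shape is not None and tissue.spacing is not None:
        sigma = correlation_length_mm / tissue.spacing / 2.0
        fld = ndimage.gaussian_filter(noise.reshape(tissue.grid_shape),
                                      sigma=sigma, mode="nearest").ravel()
    else:
        # neighbour-averaging diffusion: k sweeps ~ Gaussian of width sqrt(k)*h
        c = tissue.coupling()
        import scipy.sparse as sp
        n = tissue.n_nodes
        W = sp.csr_matrix((c.weights, c.indices, c.indptr), shape=(n, n))
        deg = np.asarray(W.sum(axis=1)).ravel()
        deg[deg == 0] = 1.0
        spacing = np.sqrt(np.median(tissue.node_area))
        k = max(1, int((correlation_length_mm / (2.0 * spacing)) ** 2))
        fld = noise
        for _ in range(k):
            fld = 0.5 * fld + 0.5 * (W @ fld) / deg
    span = fld.max() - fld.min()
    if span < 1e-12:
        fld = np.full(tissue.n_nodes, 0.5 * (lo + hi))
    else:
        fld = lo + (fld - fld.min()) * (hi - lo) / span
    return SyntheticVoltageMap(values=fld,
                               correlation_length_mm=correlation_length_mm,
                               range_mv=(lo, hi), seed=seed)
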