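"""Tissue mesh container and the discrete diffusion operator.

A :class:`TissueModel` is a triangulated surface patch with per-node lumped
areas, a scalar diffusion coefficient, and boolean scar / fibrosis masks.
Intercellular coupling is assembled once per mask configuration as a
symmetric edge-weight matrix using cotangent finite-element weights with a
lumped (barycentric) mass matrix. On structured grids triangulated with
right triangles this reduces exactly to the classical 5-point finite
difference stencil with mirrored (no-flux) boundaries, so flat sheets and
curved patches share a single code path.

The diffusion source at node i is

    s_i = d_eff / A_i * sum_j w_ij (Vm_j - Vm_i)      [mV/ms]

with d_eff = d_base / (beta * cm_area). Because w is symmetric, the
area-weighted sum of s over the mesh vanishes identically (no-flux
conservation). Edges with a scarred endpoint get zero weight; edges get one
factor of ``fibrosis_coupling_factor`` per fibrotic endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .errors import ConfigurationError, StabilityError

BETA_DEFAULT = 140.0      # membrane surface-to-volume ratio, 1/mm
CM_AREA_DEFAULT = 0.01    # membrane capacitance per unit area, uF/mm^2
WALL_THICKNESS_DEFAULT = 2.0  # mm, uniform


@dataclass
class Coupling:
    """CSR form of the symmetric edge-weight matrix plus inverse areas."""

    indptr: np.ndarray
    indices: np.ndarray
    weights: np.ndarray
    inv_area: np.ndarray


@dataclass
class TissueModel:
    """Triangulated sheet with conduction properties and lesion masks."""

    nodes: np.ndarray                 # (n, 3) mm
    triangles: np.ndarray             # (m, 3) int
    node_area: np.ndarray             # (n,) mm^2, lumped
    wall_thickness: float = WALL_THICKNESS_DEFAULT
    d_base: float = 0.126             # diffusion coefficient before beta*Cm scaling
    beta: float = BETA_DEFAULT
    cm_area: float = CM_AREA_DEFAULT
    scar_mask: np.ndarray | None = None
    fibrosis_mask: np.ndarray | None = None
    fibrosis_coupling_factor: float = 0.5
    grid_shape: Optional[tuple] = None   # (ny, nx) for structured sheets
    spacing: Optional[float] = None      # mm, for structured sheets
    _coupling: Optional[Coupling] = field(default=None, repr=False, compare=False)
    _normals: Optional[np.ndarray] = field(default=None, repr=False,
                                           compare=False)

    def __post_init__(self):
        n = self.nodes.shape[0]
        if self.scar_mask is None:
            self.scar_mask = np.zeros(n, dtype=bool)
        if self.fibrosis_mask is None:
            self.fibrosis_mask = np.zeros(n, dtype=bool)
        if np.any(self.node_area <= 0):
            raise ConfigurationError("node areas must be strictly positive")
        for name in ("beta", "cm_area", "d_base", "wall_thickness"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def d_eff(self) -> float:
        """Effective Vm diffusivity d_base / (beta * cm_area), mm^2/ms."""
        return self.d_base / (self.beta * self.cm_area)

    def with_masks(self, scar_mask=None, fibrosis_mask=None) -> "TissueModel":
        """Copy with replaced masks and invalidated coupling cache."""
        return replace(
            self,
            scar_mask=self.scar_mask if scar_mask is None else scar_mask,
            fibrosis_mask=(self.fibrosis_mask if fibrosis_mask is None
                           else fibrosis_mask),
            _coupling=None,
        )

    def coupling(self) -> Coupling:
        if self._coupling is None:
            self._coupling = _assemble_coupling(self)
        return self._coupling

    def admissible_dt(self) -> float:
        """Explicit-Euler diffusion stability bound (Gershgorin), ms."""
        c = self.coupling()
        row_sum = np.zeros(self.n_nodes)
        np.add.at(row_sum, np.repeat(np.arange(self.n_nodes),
                                     np.diff(c.indptr)), c.weights)
        lam = self.d_eff * np.max(row_sum * c.inv_area)
        if lam <= 0:
            return np.inf
        return 1.0 / lam

    def check_dt(self, dt: float) -> None:
        adm = self.admissible_dt()
        if dt > adm:
            raise StabilityError(dt, adm)

    def node_normals(self) -> np.ndarray:
        """Per-node unit normals (area-weighted triangle-normal average),
        cached — the geometry never changes after construction."""
        if self._normals is None:
            p = self.nodes
            t = self.triangles
            fn = np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]])
            nn = np.zeros_like(p)
            for c in range(3):
                np.add.at(nn, t[:, c], fn)
            norm = np.linalg.norm(nn, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            self._normals = nn / norm
        return self._normals

    def nearest_node(self, point) -> int:
        return int(np.argmin(np.linalg.norm(self.nodes - np.asarray(point),
                                            axis=1)))

    def interior_mask(self, margin_mm: float) -> np.ndarray:
        """Nodes at least ``margin_mm`` (xy, flat frame) from the bounding box."""
        p = self.nodes
        lo = p.min(axis=0)
        hi = p.max(axis=0)
        ok = np.ones(self.n_nodes, dtype=bool)
        for ax in range(2):
            ok &= (p[:, ax] >= lo[ax] + margin_mm) & (p[:, ax] <= hi[ax] - margin_mm)
        return ok


def _assemble_coupling(tissue: TissueModel) -> Coupling:
    p = tissue.nodes
    tri = tissue.triangles
    n = tissue.n_nodes
    rows, cols, vals = [], [], []
    for c in range(3):
        i = tri[:, c]
        j = tri[:, (c + 1) % 3]
        k = tri[:, (c + 2) % 3]
        u = p[j] - p[i]
        v = p[k] - p[i]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cross[cross < 1e-12] = 1e-12
        cot = np.einsum("ij,ij->i", u, v) / cross
        w = 0.5 * cot
        rows.append(j); cols.append(k); vals.append(w)
        rows.append(k); cols.append(j); vals.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)

    scar = tissue.scar_mask
    keep = ~(scar[rows] | scar[cols])
    rows, cols, vals = rows[keep], cols[keep], vals[keep]
    fib = tissue.fibrosis_mask
    if fib.any():
        factor = tissue.fibrosis_coupling_factor
        vals = vals * factor ** (fib[rows].astype(float)
                                 + fib[cols].astype(float))

    W = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    W.sum_duplicates()
    # negative summed weights can only arise on very obtuse triangulations;
    # clip to keep the operator an M-matrix (monotone scheme)
    W.data = np.maximum(W.data, 0.0)
    return Coupling(
        indptr=W.indptr.astype(np.int64),
        indices=W.indices.astype(np.int64),
        weights=W.data.astype(np.float64),
        inv_area=(1.0 / tissue.node_area).astype(np.float64),
    )


def diffusion_source(tissue: TissueModel, vm: np.ndarray) -> np.ndarray:
    """d_eff * Laplacian(vm) per node (mV/ms) — NumPy path for diagnostics."""
    c = tissue.coupling()
    n = tissue.n_nodes
    W = sp.csr_matrix((c.weights, c.indices, c.indptr), shape=(n, n))
    row_sum = np.asarray(W.sum(axis=1)).ravel()
    return tissue.d_eff * c.inv_area * (W @ vm - row_sum * vm)


def lumped_areas(nodes: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Barycentric lumped areas: one third of each incident triangle."""
    p = nodes
    t = triangles
    a = 0.5 * np.linalg.norm(
        np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]]), axis=1)
    area = np.zeros(p.shape[0])
    for c in range(3):
        np.add.at(area, t[:, c], a / 3.0)
    return area
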