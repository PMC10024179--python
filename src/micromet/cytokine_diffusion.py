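"""Continuum model of the two surrogate cytokines (ENH, SUP).

Fick's second law dc/dt = D * Laplacian(c) + f with a secretion/degradation
term f, discretized with the explicit Euler forward method on the agent
lattice (7-point Laplacian, zero-flux boundaries).  The explicit scheme is
stable for D * dt_sub / dx^2 <= 1/6 in 3D; each 10-min agent step is split
into substeps satisfying that bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels as _k
from .model_core import LatticeConfig


@dataclass
class CytokineField:
    """Per-voxel concentrations of the immunoenhancing (ENH) and
    immunosuppressive (SUP) surrogate cytokines, shaped (nz, ny, nx)."""

    enh: np.ndarray
    sup: np.ndarray

    @classmethod
    def zeros(cls, lattice: LatticeConfig) -> "CytokineField":
        nx, ny, nz = lattice.side_lengths
        return cls(np.zeros((nz, ny, nx)), np.zeros((nz, ny, nx)))

    def total_mass(self) -> tuple[float, float]:
        return float(self.enh.sum()), float(self.sup.sum())


@dataclass
class DiffusionParams:
    """Diffusion constants (um^2/min), shared first-order decay rate (1/min)
    and the number of explicit substeps per agent step (None = derived from
    the stability bound)."""

    d_enh: float = 5.0
    d_sup: float = 5.0
    lambda_decay: float = 0.02
    n_substeps: Optional[int] = None

    def __post_init__(self):
        if self.d_enh < 0 or self.d_sup < 0:
            raise ValueError("diffusion constants must be >= 0")
        if self.lambda_decay < 0:
            raise ValueError("lambda_decay must be >= 0")
        if self.n_substeps is not None and self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")

    def resolved_substeps(self, lattice: LatticeConfig) -> int:
        if self.n_substeps is not None:
            return int(self.n_substeps)
        bound = stability_check(self, lattice)
        if math.isinf(bound):
            return 1
        return max(1, int(math.ceil(lattice.dt_min / bound)))


def stability_check(params: DiffusionParams, lattice: LatticeConfig) -> float:
    """Maximum stable substep length dx^2 / (6 * D) in minutes for the 3D
    explicit scheme (worst species); +inf when both D are zero."""
    d = max(params.d_enh, params.d_sup)
    if d == 0:
        return math.inf
    return lattice.voxel_edge_um ** 2 / (6.0 * d)


def _validate_substep(params: DiffusionParams, lattice: LatticeConfig) -> tuple[float, int]:
    n_sub = params.resolved_substeps(lattice)
    dt_sub = lattice.dt_min / n_sub
    bound = stability_check(params, lattice)
    if dt_sub > bound * (1 + 1e-12):
        raise ValueError(
            f"explicit diffusion unstable: substep {dt_sub:g} min exceeds the "
            f"admissible maximum {bound:g} min; increase n_substeps"
        )
    return dt_sub, n_sub


def diffusion_step(field: CytokineField, params: DiffusionParams,
                   lattice: LatticeConfig) -> CytokineField:
    """Advance both species by one agent step (all substeps), in place.

    Each substep applies c <- c + dt_sub * (D * L(c) - lambda * c) with the
    7-point Laplacian L and no-flux boundaries.
    """
    dt_sub, n_sub = _validate_substep(params, lattice)
    nx, ny, nz = lattice.side_lengths
    dx = lattice.voxel_edge_um
    tmp = np.empty(lattice.n_voxels)
    for arr, d in ((field.enh, params.d_enh), (field.sup, params.d_sup)):
        flat = arr.reshape(-1)
        _k.diffuse(flat, d, params.lambda_decay, dt_sub, n_sub, dx, nx, ny, nz, tmp)
    return field


def deposit_secretion(field: CytokineField, sources, lattice: LatticeConfig) -> CytokineField:
    """Add one agent step of secretion: each ``(voxel, species, rate)`` source
    increases its voxel by rate * dt (rate in concentration units per minute,
    species "enh" or "sup")."""
    for voxel, species, rate in sources:
        if rate < 0:
            raise ValueError("secretion rate must be >= 0")
        x, y, z = voxel
        target = field.enh if species == "enh" else field.sup
        target[z, y, x] += rate * lattice.dt_min
    return field
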