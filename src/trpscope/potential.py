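"""Electrostatic-potential grids for tryptophan microenvironment readout.

Continuum-electrostatics codes (APBS and friends) write the potential
around a protein as a regular scalar grid in kT/e, in the OpenDX scalar
format.  This module reads and writes that dialect, samples grids by
trilinear interpolation, and generates *synthetic* grids from point
charges by screened-Coulomb (linearised Debye-Hueckel) superposition:

    phi(r) = sum_i q_i * l_B * exp(-kappa * r_i) / r_i      [kT/e]

with l_B the Bjerrum length of the solvent and 1/kappa the Debye
length.  The synthetic generator uses a single uniform solvent
dielectric - it is a desk-scale stand-in with the right length scales
and superposition structure, not a two-dielectric Poisson-Boltzmann
solution.  Grids produced by a real solver are first-class inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants
from scipy.interpolate import RegularGridInterpolator


@dataclass(frozen=True)
class SolventModel:
    """Solvent/solute continuum parameters.

    Defaults follow common practice for protein electrostatics at
    physiological salt: 0.15 M monovalent salt, 298.15 K, solute and
    solvent dielectric constants 2.0 and 78.54, 1.4 A water probe.
    """

    ionic_strength: float = 0.15  # mol/L, monovalent
    temperature: float = 298.15  # K
    eps_solute: float = 2.0
    eps_solvent: float = 78.54
    probe_radius: float = 1.4  # Angstrom

    def __post_init__(self):
        if min(
            self.temperature, self.eps_solute, self.eps_solvent, self.probe_radius
        ) <= 0 or self.ionic_strength < 0:
            raise ValueError("solvent model parameters must be positive (I >= 0)")


def bjerrum_length(model: SolventModel) -> float:
    """Bjerrum length e^2/(4 pi eps0 eps_r kB T) in Angstrom (~7.1 A in water)."""
    lb_m = constants.e**2 / (
        4.0
        * np.pi
        * constants.epsilon_0
        * model.eps_solvent
        * constants.k
        * model.temperature
    )
    return float(lb_m * 1e10)


def debye_kappa(model: SolventModel) -> float:
    """Inverse Debye screening length kappa in 1/Angstrom.

    kappa^2 = 8 pi l_B N_A I for a 1:1 salt of molar ionic strength I;
    at 0.15 M in water at 25 C the Debye length 1/kappa is ~7.9 A.
    """
    if model.ionic_strength == 0:
        return 0.0
    # ion-pair number density in 1/A^3: N_A * I[mol/L] * 1e3 / 1e30
    n = constants.N_A * model.ionic_strength * 1e3 * 1e-30
    return float(np.sqrt(8.0 * np.pi * bjerrum_length(model) * n))


def evaluate_potential(charges, points, model: SolventModel) -> np.ndarray:
    """Screened-Coulomb potential of point charges, in kT/e.

    Parameters
    ----------
    charges : sequence of (q, pos)
        Charge in units of e and position in Angstrom, or a Structure
        with ``charges``/``coords`` attributes.
    points : (N, 3) or (3,) array
        Evaluation points in Angstrom.

    Raises on a point closer than 1e-6 A to a charge.
    """
    q, pos = _charge_arrays(charges)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if q.size == 0:
        out = np.zeros(len(pts))
        return out[0] if np.ndim(points) == 1 else out
    lb = bjerrum_length(model)
    kappa = debye_kappa(model)
    d = np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=2)
    if np.any(d < 1e-6):
        raise ValueError("evaluation point coincides with a point charge")
    phi = (q[None, :] * lb * np.exp(-kappa * d) / d).sum(axis=1)
    return float(phi[0]) if np.ndim(points) == 1 else phi


def _charge_arrays(charges):
    if hasattr(charges, "charges") and hasattr(charges, "coords"):
        return np.asarray(charges.charges, float), np.asarray(charges.coords, float)
    if len(charges) == 0:
        return np.zeros(0), np.zeros((0, 3))
    q = np.array([c[0] if isinstance(c, (tuple, list)) else c["q"] for c in charges], float)
    pos = np.array(
        [c[1] if isinstance(c, (tuple, list)) else c["pos"] for c in charges], float
    )
    return q, pos.reshape(-1, 3)


@dataclass
class PotentialGrid:
    """Regular 3-D scalar grid of electrostatic potential in kT/e."""

    origin: np.ndarray  # (3,) Angstrom
    spacing: np.ndarray  # (3,) Angstrom
    values: np.ndarray  # (nx, ny, nz)
    flagged_nodes: list = field(default_factory=list)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("grid must be 3-D with at least 2 nodes per axis")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.dims[i]) for i in range(3)
        )

    def node_coords(self) -> np.ndarray:
        ax = self.axes()
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)


def grid_from_structure(
    structure,
    model: SolventModel,
    origin,
    spacing,
    dims,
) -> PotentialGrid:
    """Evaluate the screened-Coulomb potential of a charge set on a grid.

    A node coinciding with a charge is filled from its nearest
    non-coincident node and recorded in ``flagged_nodes`` - synthetic
    grids never contain infinities.
    """
    origin = np.asarray(origin, float).reshape(3)
    spacing = np.asarray(spacing, float).reshape(3)
    dims = tuple(int(d) for d in dims)
    grid = PotentialGrid(origin, spacing, np.zeros(dims))
    pts = grid.node_coords()
    q, pos = _charge_arrays(structure)
    if q.size == 0:
        return grid
    lb = bjerrum_length(model)
    kappa = debye_kappa(model)
    d = np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=2)
    bad = np.any(d < 1e-6, axis=1)
    d_safe = np.where(d < 1e-6, np.inf, d)
    phi = (q[None, :] * lb * np.exp(-kappa * d_safe) / d_safe).sum(axis=1)
    if np.any(bad):
        good_idx = np.flatnonzero(~bad)
        for i in np.flatnonzero(bad):
            j = good_idx[np.argmin(np.linalg.norm(pts[good_idx] - pts[i], axis=1))]
            phi[i] = phi[j]
            grid.flagged_nodes.append(tuple(np.unravel_index(i, dims)))
    grid.values = phi.reshape(dims)
    return grid


def sample_grid(grid: PotentialGrid, point) -> float:
    """Trilinear interpolation of the grid at a point (kT/e); exact at nodes."""
    pt = np.asarray(point, dtype=float).reshape(-1, 3)
    interp = RegularGridInterpolator(
        grid.axes(), grid.values, method="linear", bounds_error=True
    )
    try:
        out = interp(pt)
    except ValueError as exc:
        raise ValueError(f"point {point} outside grid bounding box") from exc
    return float(out[0]) if np.ndim(point) == 1 else np.asarray(out)


# ---------------------------------------------------------------------------
# OpenDX scalar-grid I/O (APBS dialect: z varies fastest, 3 values per line)


def write_dx(grid: PotentialGrid, path, comment: str = "trpscope potential grid") -> None:
    nx, ny, nz = grid.dims
    lines = [f"# {comment}"]
    lines.append(f"object 1 class gridpositions counts {nx} {ny} {nz}")
    lines.append("origin {:.6e} {:.6e} {:.6e}".format(*grid.origin))
    lines.append(f"delta {grid.spacing[0]:.6e} 0.000000e+00 0.000000e+00")
    lines.append(f"delta 0.000000e+00 {grid.spacing[1]:.6e} 0.000000e+00")
    lines.append(f"delta 0.000000e+00 0.000000e+00 {grid.spacing[2]:.6e}")
    lines.append(f"object 2 class gridconnections counts {nx} {ny} {nz}")
    lines.append(
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows"
    )
    flat = grid.values.ravel(order="C")  # z fastest
    for i in range(0, flat.size, 3):
        chunk = flat[i : i + 3]
        lines.append(" ".join(f"{v:.6e}" for v in chunk))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dx(path) -> PotentialGrid:
    """Read an OpenDX scalar grid in the APBS dialect."""
    dims = None
    origin = None
    deltas = []
    values: list[float] = []
    n_items = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith("object 1 class gridpositions"):
                dims = tuple(int(t) for t in s.split("counts", 1)[1].split())
            elif s.startswith("origin"):
                origin = [float(t) for t in s.split()[1:4]]
            elif s.startswith("delta"):
                deltas.append([float(t) for t in s.split()[1:4]])
            elif s.startswith("object 3"):
                n_items = int(s.split("items", 1)[1].split()[0])
            elif s.startswith(("object", "attribute", "component")):
                continue
            elif n_items is not None and len(values) < n_items:
                values.extend(float(t) for t in s.split())
    if dims is None or origin is None or len(deltas) != 3 or n_items is None:
        raise ValueError(f"{path}: not a recognisable OpenDX scalar grid")
    if len(values) != n_items:
        raise ValueError(f"{path}: expected {n_items} values, found {len(values)}")
    spacing = np.array([deltas[0][0], deltas[1][1], deltas[2][2]])
    off_diag = np.abs(np.array(deltas)) - np.diag(spacing)
    if np.any(np.abs(off_diag) > 1e-12):
        raise ValueError(f"{path}: non-axis-aligned grids are not supported")
    vals = np.asarray(values, dtype=float).reshape(dims, order="C")
    return PotentialGrid(np.asarray(origin), spacing, vals)
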