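"""Synthetic ground-truth inputs for the whole pipeline.

No raw measurement accompanies the analysis this package implements, so
every input is generated here with known ground truth and explicit
seeds:

* fluorophore banks - excitation/emission band profiles standing in for
  the two resolved tryptophan emission classes of a multi-Trp protein
  (buried, blue-emitting near 330 nm; anomalous, red-emitting near
  362 nm; both exciting near 282/284 nm);
* TSFS cubes - sample x excitation x offset intensity cubes built as a
  nonnegative multilinear mixture of the bank profiles, with optional
  second-order scatter ridge at lambda_em ~ 2 lambda_exc, additive
  Gaussian noise and buffer blanks;
* TCSPC decays - multi-exponential expectation curves convolved with a
  Gaussian IRF, scaled to a target peak count (20k by default, the
  usual stopping criterion) and Poisson-sampled per bin;
* toy structures - tryptophans with geometrically correct planar
  indole rings (ideal fused five/six ring, 1.40 A bonds) plus decoy
  charged atoms, writable as PDB and PQR.

Everything is bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from trpscope.mdf import TSFSCube
from trpscope.structures import Atom, Structure
from trpscope.tcspc import DecayCurve, gaussian_irf, model_decay

# ---------------------------------------------------------------------------
# fluorophore bank


@dataclass(frozen=True)
class FluorophoreComponent:
    """One emitter: excitation and emission band positions/widths (nm)."""

    name: str
    exc_max: float
    exc_width: float
    em_max: float
    em_width: float
    band_shape: str = "gaussian"

    def __post_init__(self):
        if self.em_max <= self.exc_max:
            raise ValueError(
                f"{self.name}: em_max must exceed exc_max (positive Stokes shift)"
            )
        if self.exc_width <= 0 or self.em_width <= 0:
            raise ValueError(f"{self.name}: band widths must be positive")
        if self.band_shape not in ("gaussian", "log-normal"):
            raise ValueError(f"{self.name}: unknown band shape {self.band_shape!r}")

    def _band(self, grid: np.ndarray, center: float, width: float) -> np.ndarray:
        grid = np.asarray(grid, float)
        if self.band_shape == "gaussian":
            return np.exp(-0.5 * ((grid - center) / width) ** 2)
        # log-normal: gaussian in log-wavelength, peak at `center`, red tail
        s = width / center
        out = np.zeros_like(grid)
        pos = grid > 0
        out[pos] = np.exp(-0.5 * (np.log(grid[pos] / center) / s) ** 2)
        return out

    def excitation(self, grid) -> np.ndarray:
        """Excitation profile on a wavelength grid, peak-normalised to 1."""
        return self._band(grid, self.exc_max, self.exc_width)

    def emission(self, grid) -> np.ndarray:
        """Emission profile on a wavelength grid, peak-normalised to 1."""
        return self._band(grid, self.em_max, self.em_width)


def make_component_bank(spec: list[FluorophoreComponent]) -> list[FluorophoreComponent]:
    """Validate and return a component bank (profiles peak-normalised)."""
    if not spec:
        raise ValueError("component bank must contain at least one component")
    return list(spec)


def default_trp_bank() -> list[FluorophoreComponent]:
    """The two-emitter study condition: 282/330 nm and 284/362 nm bands."""
    return make_component_bank(
        [
            FluorophoreComponent("blue_trp", 282.0, 9.0, 330.0, 22.0),
            FluorophoreComponent("red_trp", 284.0, 9.0, 362.0, 26.0),
        ]
    )


# ---------------------------------------------------------------------------
# TSFS cubes

DEFAULT_EXC_GRID = np.arange(260.0, 320.0 + 1, 2.0)  # 31 points
DEFAULT_OFFSET_GRID = np.arange(20.0, 160.0 + 1, 2.0)  # 71 points


def simulate_tsfs(
    bank: list[FluorophoreComponent],
    scores: np.ndarray,
    exc_grid: np.ndarray = DEFAULT_EXC_GRID,
    offset_grid: np.ndarray = DEFAULT_OFFSET_GRID,
    noise_sd: float = 0.0,
    scatter_on: bool = False,
    scatter_width: float = 5.0,
    scatter_amplitude: float | None = None,
    seed: int = 0,
) -> TSFSCube:
    """Simulate a TSFS cube from a component bank and sample scores.

    cube[s, e, o] = sum_k scores[s, k] exc_k(l_e) em_k(l_e + d_o),
    optionally plus a Gaussian second-order-scatter ridge along
    lambda_em = 2 lambda_exc and additive Gaussian noise.  The default
    grids (260-320 nm excitation, 20-160 nm offsets, 2 nm steps) give
    an S x 31 x 71 cube.
    """
    exc_grid = np.asarray(exc_grid, float)
    offset_grid = np.asarray(offset_grid, float)
    if exc_grid.size == 0 or offset_grid.size == 0:
        raise ValueError("wavelength grids must be nonempty")
    scores = np.atleast_2d(np.asarray(scores, float))
    if scores.shape[1] != len(bank):
        raise ValueError("scores must have one column per bank component")
    if np.any(scores < 0):
        raise ValueError("scores must be nonnegative")

    em_matrix = exc_grid[:, None] + offset_grid[None, :]  # (E, O) emission nm
    slab = np.zeros((len(bank), exc_grid.size, offset_grid.size))
    for k, comp in enumerate(bank):
        slab[k] = comp.excitation(exc_grid)[:, None] * comp._band(
            em_matrix, comp.em_max, comp.em_width
        )
    values = np.einsum("sk,keo->seo", scores, slab)

    if scatter_on:
        amp = (
            scatter_amplitude
            if scatter_amplitude is not None
            else 0.2 * max(values.max(), 1.0)
        )
        ridge = amp * np.exp(
            -0.5 * ((em_matrix - 2.0 * exc_grid[:, None]) / scatter_width) ** 2
        )
        values = values + ridge[None, :, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, values.shape)
    sample_ids = [f"s{i:02d}" for i in range(scores.shape[0])]
    return TSFSCube(sample_ids, exc_grid, offset_grid, values)


def simulate_blank_tsfs(
    exc_grid: np.ndarray = DEFAULT_EXC_GRID,
    offset_grid: np.ndarray = DEFAULT_OFFSET_GRID,
    n_samples: int = 1,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> TSFSCube:
    """Buffer-only cube (noise, no emitters) for subtraction tests."""
    bank = default_trp_bank()
    return simulate_tsfs(
        bank,
        np.zeros((n_samples, len(bank))),
        exc_grid,
        offset_grid,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# TCSPC decays


@dataclass(frozen=True)
class DecayGroundTruth:
    """Ground truth for one synthetic decay channel.

    ``amplitudes`` are pre-exponential weights (dimensionless); the
    expectation curve is rescaled so its maximum equals
    ``peak_counts`` before Poisson sampling.
    """

    lifetimes: tuple
    amplitudes: tuple
    irf_fwhm: float = 0.5  # ns
    peak_counts: int = 20000
    time_range: float = 25.0  # ns
    n_bins: int = 1024
    background: float = 0.0  # counts per bin, added to the expectation

    def __post_init__(self):
        taus = np.asarray(self.lifetimes, float)
        amps = np.asarray(self.amplitudes, float)
        if taus.shape != amps.shape:
            raise ValueError("lifetimes and amplitudes must have equal length")
        if np.any(taus <= 0):
            raise ValueError("lifetimes must be strictly positive")
        if len(set(np.round(taus, 12))) != taus.size:
            raise ValueError("lifetimes must be distinct")
        if np.any(amps < 0) or amps.sum() <= 0:
            raise ValueError("amplitudes must be nonnegative with positive sum")
        if self.n_bins < 2 * taus.size + 2:
            raise ValueError("n_bins smaller than the number of free fit parameters")

    def time_bins(self) -> np.ndarray:
        dt = self.time_range / self.n_bins
        return dt / 2 + dt * np.arange(self.n_bins)


def decay_expectation(truth: DecayGroundTruth) -> np.ndarray:
    """Noise-free expected counts per bin (peak scaled to peak_counts)."""
    t = truth.time_bins()
    irf = gaussian_irf(t, truth.irf_fwhm) if truth.irf_fwhm > 0 else None
    expect = model_decay(
        {"taus": list(truth.lifetimes), "amps": list(truth.amplitudes)}, irf, t
    )
    expect = expect * (truth.peak_counts / expect.max())
    return expect + truth.background


def simulate_decay(
    truth: DecayGroundTruth,
    seed: int = 0,
    channel_id: int = 1,
    em_range: tuple = (300.0, 312.5),
    poisson: bool = True,
) -> DecayCurve:
    """Poisson-sample a decay histogram from its expectation curve."""
    expect = decay_expectation(truth)
    if poisson:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expect)
    else:
        counts = np.round(expect).astype(int)
    return DecayCurve(channel_id, em_range, truth.time_bins(), counts)


def default_channels(n: int = 16, start_nm: float = 300.0, width_nm: float = 12.5):
    """Emission channel ranges: n channels of width 12.5 nm from 300 nm."""
    return [
        (i + 1, (start_nm + i * width_nm, start_nm + (i + 1) * width_nm))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# toy structures


def _ideal_indole_coords() -> dict[str, np.ndarray]:
    """Planar fused 6/5 ring with 1.40 A bonds, in the z=0 plane.

    Benzene hexagon and pyrrole pentagon share the CE2-CD2 edge; the
    resulting benzene->pyrrole centroid separation is ~2.17 A.
    """
    bond = 1.40
    r6 = bond
    c6 = np.array([-bond * np.cos(np.pi / 6), 0.0])  # hexagon center
    hex_names = ["CE2", "CZ2", "CH2", "CZ3", "CE3", "CD2"]
    coords: dict[str, np.ndarray] = {}
    for name, deg in zip(hex_names, (30, 90, 150, 210, 270, 330)):
        a = np.deg2rad(deg)
        coords[name] = np.array([c6[0] + r6 * np.cos(a), c6[1] + r6 * np.sin(a), 0.0])
    r5 = bond / (2.0 * np.sin(np.pi / 5))
    c5 = np.array([r5 * np.cos(np.pi / 5), 0.0])  # pentagon center (apothem check)
    # place so shared vertices coincide with hexagon's CE2/CD2
    c5 = np.array([np.sqrt(r5**2 - coords["CE2"][1] ** 2), 0.0])
    pent = {"CE2": 144, "NE1": 72, "CD1": 0, "CG": 288, "CD2": 216}
    for name, deg in pent.items():
        if name in ("CE2", "CD2"):
            continue
        a = np.deg2rad(deg)
        coords[name] = np.array([c5[0] + r5 * np.cos(a), c5[1] + r5 * np.sin(a), 0.0])
    # CB attached to CG, in plane, pointing away from the pentagon center
    cg = coords["CG"]
    direction = cg[:2] - c5
    direction = direction / np.linalg.norm(direction)
    coords["CB"] = np.array([*(cg[:2] + 1.53 * direction), 0.0])
    return coords


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    quat = rng.normal(size=4)
    return Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()


def make_toy_structure(
    n_trp: int,
    n_decoy_atoms: int = 0,
    charge_scheme: str = "random",
    seed: int = 0,
    spread: float = 15.0,
) -> Structure:
    """A toy protein: n_trp ideal indole rings plus decoy charged atoms.

    Tryptophans are placed and oriented randomly (rigid-body) on chain
    A; decoy atoms (resname DEC) are scattered within ``spread`` A of
    the origin with charges set by ``charge_scheme`` ("zero" or
    "random" +/-0.5 e) and radii 1.5-1.9 A.
    """
    if n_trp < 1:
        raise ValueError("n_trp must be >= 1")
    if charge_scheme not in ("zero", "random"):
        raise ValueError("charge_scheme must be 'zero' or 'random'")
    rng = np.random.default_rng(seed)
    template = _ideal_indole_coords()
    atoms: list[Atom] = []
    for resnum in range(1, n_trp + 1):
        rot = _random_rotation(rng)
        offset = rng.uniform(-spread, spread, 3) if n_trp > 1 else np.zeros(3)
        for name, pos in template.items():
            atoms.append(
                Atom(
                    name,
                    "N" if name.startswith("N") else "C",
                    "TRP",
                    resnum,
                    "A",
                    rot @ pos + offset,
                    charge=0.0,
                    radius=1.55 if name.startswith("N") else 1.70,
                )
            )
    for i in range(n_decoy_atoms):
        q = 0.0 if charge_scheme == "zero" else float(rng.uniform(-0.5, 0.5))
        atoms.append(
            Atom(
                "C",
                "C",
                "DEC",
                1000 + i,
                "X",
                rng.uniform(-spread, spread, 3),
                charge=q,
                radius=float(rng.uniform(1.5, 1.9)),
            )
        )
    return Structure(atoms, source_format="PQR")
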