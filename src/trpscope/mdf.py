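"""Multi-dimensional fluorescence: TSFS cubes, t-EEM layout and PARAFAC.

A total-synchronous-fluorescence (TSFS) measurement scans excitation
and records emission at a fixed wavelength offset, giving a cube over
(sample, lambda_exc, delta_lambda).  That layout is not trilinear in
(sample, excitation, emission), so before factor analysis each datum at
(lambda_exc, delta_lambda) is re-laid onto the emission axis at
lambda_em = lambda_exc + delta_lambda ("t-EEM").  Cells of the t-EEM
grid with no source data form a missing-value mask that all fits must
respect.

The decomposition is PARAFAC: the cube is modelled as a sum of K
rank-one components score_k (x) exc_k (x) em_k, fitted by alternating
least squares with nonnegativity (HALS updates) and EM-style handling
of the missing mask (masked cells are refilled from the current model
each sweep, which maximises the observed-data least-squares
objective).  Component validity is judged with the core-consistency
diagnostic: the least-squares Tucker core given the PARAFAC loadings
is compared with the ideal superdiagonal target; values near 100%
support the chosen K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter


@dataclass
class TSFSCube:
    """Raw TSFS data: samples x excitation (nm) x offset (nm)."""

    sample_ids: list
    exc_grid: np.ndarray
    offset_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.exc_grid = np.asarray(self.exc_grid, float)
        self.offset_grid = np.asarray(self.offset_grid, float)
        self.values = np.asarray(self.values, float)
        for g in (self.exc_grid, self.offset_grid):
            if g.size == 0 or np.any(np.diff(g) <= 0):
                raise ValueError("wavelength grids must be nonempty and increasing")
        expected = (len(self.sample_ids), self.exc_grid.size, self.offset_grid.size)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TSFS values must be finite")


@dataclass
class EEMCube:
    """Trilinear (t-EEM) layout: samples x excitation x emission, with mask.

    ``missing_mask`` is True where the cell has no source data; masked
    cells never influence any fit.
    """

    sample_ids: list
    exc_grid: np.ndarray
    em_grid: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self):
        self.exc_grid = np.asarray(self.exc_grid, float)
        self.em_grid = np.asarray(self.em_grid, float)
        self.values = np.asarray(self.values, float)
        self.missing_mask = np.asarray(self.missing_mask, bool)
        if np.any(np.diff(self.em_grid) <= 0) or np.any(np.diff(self.exc_grid) <= 0):
            raise ValueError("grids must be strictly increasing")
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")

    @property
    def observed(self) -> np.ndarray:
        return ~self.missing_mask


def tsfs_to_teem(cube: TSFSCube, em_grid: np.ndarray | None = None) -> EEMCube:
    """Re-lay a TSFS cube onto the trilinear emission axis.

    Each (lambda_exc, delta) datum maps to lambda_em = lambda_exc +
    delta; per excitation row the data are linearly interpolated onto
    ``em_grid`` and cells outside the measured offset span are masked.
    """
    lo = cube.exc_grid.min() + cube.offset_grid.min()
    hi = cube.exc_grid.max() + cube.offset_grid.max()
    if em_grid is None:
        step = float(np.median(np.diff(cube.offset_grid)))
        em_grid = np.arange(lo, hi + step / 2, step)
    em_grid = np.asarray(em_grid, float)
    if em_grid[0] > lo + 1e-9 or em_grid[-1] < hi - 1e-9:
        raise ValueError(
            f"em_grid must cover [{lo}, {hi}] nm (got [{em_grid[0]}, {em_grid[-1]}])"
        )
    S, E = len(cube.sample_ids), cube.exc_grid.size
    M = em_grid.size
    values = np.zeros((S, E, M))
    mask = np.ones((S, E, M), bool)
    for j, exc in enumerate(cube.exc_grid):
        em_src = exc + cube.offset_grid
        inside = (em_grid >= em_src[0] - 1e-9) & (em_grid <= em_src[-1] + 1e-9)
        if not inside.any():
            continue
        for i in range(S):
            values[i, j, inside] = np.interp(
                em_grid[inside], em_src, cube.values[i, j, :]
            )
        mask[:, j, inside] = False
    if mask.all():
        raise ValueError("no overlap between TSFS data and the emission grid")
    return EEMCube(list(cube.sample_ids), cube.exc_grid.copy(), em_grid, values, mask)


def preprocess_teem(
    c: EEMCube,
    blank: EEMCube | None = None,
    scatter_window: float = 10.0,
    sg_window: int = 7,
    sg_order: int = 2,
) -> EEMCube:
    """Blank subtraction, second-order-scatter removal and smoothing.

    Cells within ``scatter_window`` nm of the second-order scatter line
    lambda_em = 2*lambda_exc are replaced by linear interpolation along
    the emission axis from the flanking signal; each (sample,
    excitation) emission row is then Savitzky-Golay smoothed on its
    contiguous unmasked support.  The missing mask is propagated
    unchanged.
    """
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValueError("sg_window must be odd and greater than sg_order")
    values = c.values.copy()
    if blank is not None:
        if (
            blank.values.shape != c.values.shape
            or not np.allclose(blank.exc_grid, c.exc_grid)
            or not np.allclose(blank.em_grid, c.em_grid)
        ):
            raise ValueError("blank cube grids do not match")
        values = values - blank.values
    obs = c.observed
    for j, exc in enumerate(c.exc_grid):
        in_band = np.abs(c.em_grid - 2.0 * exc) <= scatter_window
        for i in range(values.shape[0]):
            row_obs = obs[i, j]
            band = in_band & row_obs
            keep = row_obs & ~in_band
            if band.any() and keep.sum() >= 2:
                values[i, j, band] = np.interp(
                    c.em_grid[band], c.em_grid[keep], values[i, j, keep]
                )
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            idx = np.flatnonzero(obs[i, j])
            if idx.size >= sg_window:
                seg = slice(idx[0], idx[-1] + 1)
                values[i, j, seg] = savgol_filter(values[i, j, seg], sg_window, sg_order)
    return EEMCube(
        list(c.sample_ids), c.exc_grid.copy(), c.em_grid.copy(), values,
        c.missing_mask.copy(),
    )


@dataclass
class ParafacModel:
    """A fitted PARAFAC model with unit-peak loadings.

    Scale indeterminacy is resolved by peak-normalising the excitation
    and emission loadings and absorbing magnitudes into the sample
    scores; permutation indeterminacy by sorting components by
    ascending emission-loading argmax.
    """

    n_components: int
    sample_scores: np.ndarray  # S x K, >= 0
    exc_loadings: np.ndarray  # E x K, unit peak
    em_loadings: np.ndarray  # M x K, unit peak
    exc_grid: np.ndarray
    em_grid: np.ndarray
    fit_residual_fraction: float
    converged: bool
    n_iter: int
    core_consistency: float | None = None

    def reconstruct(self) -> np.ndarray:
        return np.einsum(
            "sk,ek,mk->sem", self.sample_scores, self.exc_loadings, self.em_loadings
        )


def _fill_missing(c: EEMCube, model_values: np.ndarray | None) -> np.ndarray:
    x = np.where(c.missing_mask, 0.0, c.values)
    if model_values is not None:
        x = np.where(c.missing_mask, model_values, x)
    return x


def _hals_sweep(x: np.ndarray, A: np.ndarray, B: np.ndarray, C: np.ndarray, nonneg: bool):
    """One ALS sweep over the three modes (HALS column updates)."""
    eps = 1e-12
    for mode, (F, G1, G2) in enumerate(((A, B, C), (B, A, C), (C, A, B))):
        gram = (G1.T @ G1) * (G2.T @ G2)
        if mode == 0:
            mttkrp = np.einsum("sem,ek,mk->sk", x, B, C)
        elif mode == 1:
            mttkrp = np.einsum("sem,sk,mk->ek", x, A, C)
        else:
            mttkrp = np.einsum("sem,sk,ek->mk", x, A, B)
        if nonneg:
            for k in range(F.shape[1]):
                num = mttkrp[:, k] - F @ gram[:, k] + F[:, k] * gram[k, k]
                F[:, k] = np.maximum(num / max(gram[k, k], eps), 0.0)
                if F[:, k].max() <= eps:  # dead component: reseed tiny
                    F[:, k] = eps
        else:
            F[:] = np.linalg.solve(gram + eps * np.eye(gram.shape[0]), mttkrp.T).T
    return A, B, C


def parafac_fit(
    c: EEMCube,
    K: int,
    nonneg: bool = True,
    tol: float = 1e-8,
    max_iter: int = 2000,
    n_starts: int = 10,
    seed: int = 0,
) -> ParafacModel:
    """Fit a K-component PARAFAC model to a (possibly masked) t-EEM cube.

    Best of ``n_starts`` random nonnegative initialisations by observed
    residual; non-convergence is flagged on the result, not raised.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    obs = c.observed
    if obs.sum() < K * sum(c.values.shape):
        raise ValueError("not enough unmasked data for the requested K")
    rng = np.random.default_rng(seed)
    x_obs = np.where(obs, c.values, 0.0)
    norm_obs = float(np.sum(x_obs**2)) or 1.0
    S, E, M = c.values.shape

    best = None
    for _ in range(max(n_starts, 1)):
        A = rng.uniform(0.1, 1.0, (S, K))
        B = rng.uniform(0.1, 1.0, (E, K))
        C = rng.uniform(0.1, 1.0, (M, K))
        model_values = None
        prev = np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            x = _fill_missing(c, model_values)
            A, B, C = _hals_sweep(x, A, B, C, nonneg)
            model_values = np.einsum("sk,ek,mk->sem", A, B, C)
            res = float(np.sum(((c.values - model_values) * obs) ** 2)) / norm_obs
            if np.isfinite(prev) and abs(prev - res) <= tol:
                converged = True
                break
            prev = res
        if best is None or res < best[0]:
            best = (res, A.copy(), B.copy(), C.copy(), converged, it)

    res, A, B, C, converged, it = best
    # absorb loading magnitudes into scores, unit-peak loadings
    for F in (B, C):
        peaks = F.max(axis=0)
        peaks[peaks == 0] = 1.0
        A *= peaks
        F /= peaks
    order = np.argsort(np.argmax(C, axis=0), kind="stable")
    return ParafacModel(
        n_components=K,
        sample_scores=A[:, order],
        exc_loadings=B[:, order],
        em_loadings=C[:, order],
        exc_grid=c.exc_grid.copy(),
        em_grid=c.em_grid.copy(),
        fit_residual_fraction=res,
        converged=converged,
        n_iter=it,
    )


def core_consistency(m: ParafacModel, c: EEMCube) -> float:
    """CONCORDIA: 100*(1 - ||G - T||^2/||T||^2).

    G is the least-squares Tucker core given the PARAFAC loadings
    (computed mode-wise with pseudoinverses), T the superdiagonal
    target of ones.  Masked cells are filled from the model before the
    core is estimated.
    """
    x = np.where(c.missing_mask, m.reconstruct(), c.values)
    Ap = np.linalg.pinv(m.sample_scores)
    Bp = np.linalg.pinv(m.exc_loadings)
    Cp = np.linalg.pinv(m.em_loadings)
    G = np.einsum("ks,sem->kem", Ap, x)
    G = np.einsum("le,kem->klm", Bp, G)
    G = np.einsum("nm,klm->kln", Cp, G)
    K = m.n_components
    T = np.zeros((K, K, K))
    for k in range(K):
        T[k, k, k] = 1.0
    return float(100.0 * (1.0 - np.sum((G - T) ** 2) / np.sum(T**2)))


def select_n_components(
    c: EEMCube,
    k_max: int = 3,
    threshold_percent: float = 90.0,
    min_rel_improvement: float = 0.05,
    noise_residual_floor: float = 0.5,
    **fit_kwargs,
) -> dict:
    """Pick the number of components by core consistency + residual drop.

    Returns ``{"K", "diagnostics", "warning"}``; K is the largest
    component count whose core consistency stays above the threshold
    and whose residual improves on K-1 by at least the configured
    relative amount.  A fit that explains less than half the variance
    at the chosen K raises the ``no_structure`` warning.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    rows = []
    models = {}
    for k in range(1, k_max + 1):
        m = parafac_fit(c, k, **fit_kwargs)
        m.core_consistency = core_consistency(m, c)
        models[k] = m
        rows.append(
            {
                "K": k,
                "core_consistency": m.core_consistency,
                "residual_fraction": m.fit_residual_fraction,
                "converged": m.converged,
            }
        )
    diag = pd.DataFrame(rows)
    chosen = 1
    for k in range(2, k_max + 1):
        prev = models[k - 1].fit_residual_fraction
        cur = models[k].fit_residual_fraction
        improved = cur <= (1.0 - min_rel_improvement) * prev
        if models[k].core_consistency >= threshold_percent and improved:
            chosen = k
        else:
            break
    warning = None
    if models[chosen].fit_residual_fraction > noise_residual_floor:
        warning = "no_structure"
    return {"K": chosen, "diagnostics": diag, "warning": warning, "model": models[chosen]}


def summarize_components(m: ParafacModel) -> pd.DataFrame:
    """Per-component excitation/emission maxima (nm) and score shares."""
    shares = m.sample_scores.sum(axis=0)
    total = shares.sum() or 1.0
    rows = [
        {
            "component": k + 1,
            "exc_max": float(m.exc_grid[int(np.argmax(m.exc_loadings[:, k]))]),
            "em_max": float(m.em_grid[int(np.argmax(m.em_loadings[:, k]))]),
            "score_share": float(shares[k] / total),
        }
        for k in range(m.n_components)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# long-format TSFS text I/O


def write_tsfs_long(cube: TSFSCube, path) -> None:
    S, E, O = cube.values.shape
    sample = np.repeat(cube.sample_ids, E * O)
    exc = np.tile(np.repeat(cube.exc_grid, O), S)
    off = np.tile(cube.offset_grid, S * E)
    pd.DataFrame(
        {
            "sample": sample,
            "lambda_exc_nm": exc,
            "delta_lambda_nm": off,
            "intensity": cube.values.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def read_tsfs_long(path) -> TSFSCube:
    df = pd.read_csv(path, sep="\t")
    samples = list(pd.unique(df["sample"]))
    exc = np.sort(df["lambda_exc_nm"].unique())
    off = np.sort(df["delta_lambda_nm"].unique())
    values = (
        df.set_index(["sample", "lambda_exc_nm", "delta_lambda_nm"])["intensity"]
        .unstack(["lambda_exc_nm", "delta_lambda_nm"])  # keeps sample order
        .loc[samples]
        .to_numpy()
        .reshape(len(samples), exc.size, off.size)
    )
    return TSFSCube(samples, exc, off, values)
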