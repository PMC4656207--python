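"""Simplified automatic model building: peak picking and greedy
pseudo-C-alpha chain tracing, plus conversion of the traced model into a
phase source with sigma-A figures of merit.

This is a deliberately minimal stand-in for a full main-/side-chain builder:
pseudo-atoms at C-alpha spacing carry enough phase information to drive the
phase-extension loop at the scale this package targets.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import maximum_filter

from .core import (
    AtomModel,
    MAIN_CHAIN,
    MapGrid,
    ReflectionSet,
    SymmetryOps,
    UnitCell,
    structure_factors_from_model,
)
from . import sigmaa as _sigmaa

__all__ = ["find_peaks", "trace_ca_chain", "ca_recovery", "phases_from_built_model"]

CA_SPACING = 3.8  # A, canonical C-alpha / C-alpha distance


def find_peaks(map_: MapGrid, sigma_cut: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima above mean + sigma_cut * std, sub-voxel refined.

    Returns (positions (N,3) Cartesian A, heights), sorted by height
    descending.  Sub-voxel refinement fits a 1-D quadratic along each axis.
    """
    rho = map_.rho
    thr = rho.mean() + sigma_cut * rho.std()
    local_max = rho >= maximum_filter(rho, size=3, mode="wrap")
    sel = local_max & (rho > thr)
    if not sel.any():
        return np.empty((0, 3)), np.empty(0)
    idx = np.argwhere(sel)
    shape = np.array(map_.shape)
    offsets = np.zeros((len(idx), 3))
    for ax in range(3):
        up = idx.copy()
        up[:, ax] = (idx[:, ax] + 1) % shape[ax]
        dn = idx.copy()
        dn[:, ax] = (idx[:, ax] - 1) % shape[ax]
        f0 = rho[tuple(idx.T)]
        fp = rho[tuple(up.T)]
        fm = rho[tuple(dn.T)]
        denom = fm - 2.0 * f0 + fp
        with np.errstate(divide="ignore", invalid="ignore"):
            off = np.where(np.abs(denom) > 1e-12, 0.5 * (fm - fp) / denom, 0.0)
        offsets[:, ax] = np.clip(off, -0.5, 0.5)
    frac = (idx + offsets) / shape
    cart = map_.cell.orthogonalize(frac)
    heights = rho[tuple(idx.T)]
    order = np.lexsort((cart[:, 2], cart[:, 1], cart[:, 0], -heights))
    return cart[order], heights[order]


def trace_ca_chain(
    peaks: np.ndarray,
    heights: np.ndarray | None = None,
    spacing: float = CA_SPACING,
    tol: float = 0.7,
    min_chain: int = 4,
) -> AtomModel:
    """Greedy chain tracing through candidate C-alpha positions.

    Starting from the highest unused peak, repeatedly append the
    highest-scoring unused peak at distance spacing +/- tol, extending the
    chain at both ends; chains shorter than ``min_chain`` are discarded.
    Determinism: ties broken by height then lexicographic position.
    """
    from scipy.spatial import cKDTree

    peaks = np.asarray(peaks, float).reshape(-1, 3)
    n = len(peaks)
    if heights is None:
        heights = np.ones(n)
    heights = np.asarray(heights, float)
    order = np.lexsort((peaks[:, 2], peaks[:, 1], peaks[:, 0], -heights))
    peaks, heights = peaks[order], heights[order]

    used = np.zeros(n, bool)
    tree = cKDTree(peaks) if n else None
    chains: list[list[int]] = []

    def best_next(i: int) -> int | None:
        cand = tree.query_ball_point(peaks[i], spacing + tol)
        best, best_h = None, -np.inf
        for j in cand:
            if used[j] or j == i:
                continue
            dist = np.linalg.norm(peaks[j] - peaks[i])
            if spacing - tol <= dist <= spacing + tol and heights[j] > best_h:
                best, best_h = j, heights[j]
        return best

    for start in range(n):
        if used[start]:
            continue
        used[start] = True
        chain = [start]
        # grow forward then backward
        for endpick in (lambda: chain[-1], lambda: chain[0]):
            while True:
                nxt = best_next(endpick())
                if nxt is None:
                    break
                used[nxt] = True
                if endpick() == chain[-1]:
                    chain.append(nxt)
                else:
                    chain.insert(0, nxt)
        if len(chain) >= min_chain:
            chains.append(chain)
        else:
            for j in chain:
                if j != start:
                    used[j] = False  # short fragments release their members
            # the failed start stays used so the scan terminates

    if not chains:
        return AtomModel(element=[], xyz=np.empty((0, 3)), B=np.empty(0),
                         occ=np.empty(0))
    xyz, chain_ids, resnum = [], [], []
    for ci, chain in enumerate(chains):
        name = chr(ord("A") + ci % 26)
        for ri, j in enumerate(chain, start=1):
            xyz.append(peaks[j])
            chain_ids.append(name)
            resnum.append(ri)
    m = len(xyz)
    return AtomModel(
        element=["X"] * m,
        xyz=np.array(xyz),
        B=np.full(m, 30.0),
        occ=np.ones(m),
        chain=chain_ids,
        resnum=np.array(resnum),
        role=[MAIN_CHAIN] * m,
    )


def ca_recovery(
    built: AtomModel,
    truth: AtomModel,
    cell: UnitCell | None = None,
    sym: SymmetryOps | None = None,
    cutoff: float = 1.5,
    search_origin: bool = True,
) -> float:
    """Fraction of built atoms within ``cutoff`` A of a true main-chain atom.

    Crystal symmetry is applied to the truth; in P1 (arbitrary origin) the
    best origin shift on a ~1 A grid is found first via FFT cross-correlation
    of Gaussian-smeared atom rasters, then scoring uses a periodic KD-tree.
    Without a cell, plain Euclidean nearest-neighbour matching is used.
    """
    from scipy.spatial import cKDTree

    if len(built) == 0:
        return 0.0
    truth_mc = truth.select(truth.role_mask(MAIN_CHAIN))
    if len(truth_mc) == 0:
        raise ValueError("truth model has no main-chain atoms")

    if cell is None:
        tree = cKDTree(truth_mc.xyz)
        d, _ = tree.query(built.xyz)
        return float(np.mean(d <= cutoff))

    sym = sym or SymmetryOps.p1()
    frac_t = [np.mod(cell.fractionalize(truth_mc.xyz) @ R.T + t, 1.0) for R, t in sym]
    frac_truth = np.vstack(frac_t)
    frac_built = np.mod(cell.fractionalize(built.xyz), 1.0)

    shift = np.zeros(3)
    if search_origin:
        shift = _best_origin_shift(frac_built, frac_truth, cell)

    if cell.is_orthogonal():
        box = np.array([cell.a, cell.b, cell.c])
        tree = cKDTree(np.mod(frac_truth, 1.0) * box, boxsize=box)
        pts = np.mod(frac_built + shift, 1.0) * box
        d, _ = tree.query(pts, workers=-1)
    else:
        shifts = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1])).T.reshape(-1, 3)
        imgs = cell.orthogonalize((frac_truth[None] + shifts[:, None]).reshape(-1, 3))
        tree = cKDTree(imgs)
        d, _ = tree.query(cell.orthogonalize(np.mod(frac_built + shift, 1.0)))
    return float(np.mean(d <= cutoff))


def _best_origin_shift(
    frac_a: np.ndarray, frac_b: np.ndarray, cell: UnitCell, grid_step: float = 1.0
) -> np.ndarray:
    """Fractional shift s maximizing overlap of a+s with b, via FFT
    cross-correlation of smeared atom rasters on a ~grid_step A grid."""
    from scipy.fft import fftn, ifftn

    n = tuple(max(8, int(np.ceil(L / grid_step))) for L in (cell.a, cell.b, cell.c))

    def raster(frac: np.ndarray) -> np.ndarray:
        g = np.zeros(n)
        idx = np.floor(frac * np.array(n)).astype(int) % np.array(n)
        np.add.at(g, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
        from scipy.ndimage import gaussian_filter

        return gaussian_filter(g, sigma=1.0, mode="wrap")

    A, B = raster(frac_a), raster(frac_b)
    cc = np.real(fftn(np.conj(ifftn(A)) * ifftn(B)))
    best = np.unravel_index(np.argmax(cc), cc.shape)
    return np.array(best) / np.array(n)


def phases_from_built_model(
    built: AtomModel,
    obs: ReflectionSet,
    cell: UnitCell | None = None,
    sym: SymmetryOps | None = None,
    b_factor: float = 30.0,
    n_shells: int = 15,
) -> ReflectionSet:
    """Phases from the auto-built model with sigma-A figures of merit.

    Structure factors are computed by direct summation over dummy scatterers
    at uniform B; the FOM per reflection comes from shellwise sigma-A between
    the observed and model amplitudes, so a poor model weighs itself down.
    """
    if len(built) == 0:
        raise ValueError("no atoms to phase")
    cell = cell or obs.cell
    model = built.select(np.arange(len(built)))
    model.B = np.full(len(model), float(b_factor))
    calc = structure_factors_from_model(model, cell, sym, hkl=obs.hkl)
    e_obs = _sigmaa.normalize_amplitudes(obs, n_shells)
    e_calc = _sigmaa.normalize_amplitudes(calc, n_shells)
    sigA = _sigmaa.estimate_sigma_a(e_obs, e_calc, n_shells)
    centric = (sym or SymmetryOps.p1()).is_centric(obs.hkl)
    fom = _sigmaa.fom_from_sigma_a(sigA, e_obs.F, e_calc.F, obs.d, centric)
    return obs.copy(phi=calc.phi.copy(), fom=fom)
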