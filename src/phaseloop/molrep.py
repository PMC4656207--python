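"""Molecular replacement of a boxed EM map against observed amplitudes.

Desk-scale exhaustive search: the rotation function scores the Pearson
correlation between observed amplitudes and the boxed map's molecular
transform sampled at rotated reciprocal points (trilinear interpolation in
reciprocal space); the translation function builds symmetry-expanded
structure factors via the phase-shift theorem and scores the same
correlation on a fractional grid.  The significance of the top translation
is reported as a Z-score over the score distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import ifftn
from scipy.ndimage import map_coordinates

from .core import MapGrid, ReflectionSet, SymmetryOps, UnitCell

__all__ = [
    "Placement",
    "euler_to_matrix",
    "rotation_geodesic_deg",
    "euler_grid",
    "rotation_search",
    "translation_search",
    "mr_z_score",
    "apply_placement",
]


@dataclass
class Placement:
    """A candidate MR solution: orientation, fractional position, and scores."""

    rotation: np.ndarray
    translation: np.ndarray
    score: float
    z_score: float | None = None
    euler_deg: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.mod(np.asarray(self.translation, float).reshape(3), 1.0)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("placement rotation must be orthonormal")

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.ravel().tolist(),
            "translation": self.translation.tolist(),
            "score": float(self.score),
            "z_score": None if self.z_score is None else float(self.z_score),
            "euler_deg": None if self.euler_deg is None else list(self.euler_deg),
        }


def euler_to_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """ZYZ Euler angles (degrees) to a rotation matrix: Rz(a) Ry(b) Rz(g)."""

    def rz(t: float) -> np.ndarray:
        c, s = np.cos(np.radians(t)), np.sin(np.radians(t))
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])

    def ry(t: float) -> np.ndarray:
        c, s = np.cos(np.radians(t)), np.sin(np.radians(t))
        return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])

    return rz(alpha) @ ry(beta) @ rz(gamma)


def rotation_geodesic_deg(R1: np.ndarray, R2: np.ndarray) -> float:
    """Geodesic angle (degrees) between two rotations."""
    tr = np.trace(np.asarray(R1) @ np.asarray(R2).T)
    return float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))


def euler_grid(step: float) -> list[tuple[float, float, float]]:
    """Uniform-ish ZYZ grid: beta sampled every ``step`` degrees, alpha spacing
    widened by 1/sin(beta) to avoid pole oversampling, gamma every step."""
    out: list[tuple[float, float, float]] = []
    for beta in np.arange(0.0, 180.0 + 1e-9, step):
        sb = np.sin(np.radians(beta))
        n_alpha = max(1, int(round(360.0 * sb / step)))
        alphas = np.arange(n_alpha) * (360.0 / n_alpha)
        for alpha in alphas:
            for gamma in np.arange(0.0, 360.0 - 1e-9, step):
                out.append((float(alpha), float(beta), float(gamma)))
    return out


class _MolecularTransform:
    """Complex Fourier transform of a boxed map, phase-referenced to the box
    center, sampled at arbitrary reciprocal vectors by trilinear interpolation."""

    def __init__(self, em_map: MapGrid):
        self.cell = em_map.cell
        coeffs = ifftn(em_map.rho, workers=-1) * em_map.cell.volume
        nx, ny, nz = em_map.shape
        h = np.fft.fftfreq(nx) * nx
        k = np.fft.fftfreq(ny) * ny
        l = np.fft.fftfreq(nz) * nz
        hh, kk, ll = np.meshgrid(h, k, l, indexing="ij", sparse=True)
        # shift origin to the box center so the transform phase is smooth
        center = np.array([0.5, 0.5, 0.5])
        shift = np.exp(-2j * np.pi * (hh * center[0] + kk * center[1] + ll * center[2]))
        g = coeffs * shift
        self.re = np.real(g)
        self.im = np.imag(g)
        self.orth = em_map.cell.orth_matrix()
        self.shape = np.array(em_map.shape)

    def sample(self, s_cart: np.ndarray) -> np.ndarray:
        """Complex transform values at reciprocal vectors (rows, A^-1)."""
        hbox = s_cart @ self.orth  # continuous Miller coords of the box
        idx = np.mod(hbox, self.shape).T
        re = map_coordinates(self.re, idx, order=1, mode="grid-wrap")
        im = map_coordinates(self.im, idx, order=1, mode="grid-wrap")
        return re + 1j * im


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / den) if den > 0 else 0.0


def _select_range(obs: ReflectionSet, d_range: tuple[float, float] | None) -> ReflectionSet:
    if d_range is None:
        return obs
    d_lo, d_hi = max(d_range), min(d_range)
    d = obs.d
    if d.max() < d_lo - 1e-6 or d.min() > d_hi + 1e-6:
        raise ValueError(
            f"requested resolution range {d_lo:g}-{d_hi:g} A outside observed "
            f"coverage {d.max():g}-{d.min():g} A"
        )
    sel = (d <= d_lo) & (d >= d_hi)
    if not sel.any():
        raise ValueError("no observed reflections in requested resolution range")
    return obs.select(sel)


def rotation_search(
    obs: ReflectionSet,
    em_map: MapGrid,
    angular_step: float = 15.0,
    d_range: tuple[float, float] | None = None,
    refine: bool = True,
    top_n: int = 10,
) -> list[tuple[tuple[float, float, float], np.ndarray, float]]:
    """Exhaustive rotation function.

    For every rotation on the ZYZ Euler grid, the boxed map's molecular
    transform is sampled at the rotated reciprocal points of the observed
    reflections and scored by amplitude Pearson correlation.  A second pass
    refines the ``top_n`` candidates at a quarter of the step.  Returns
    (euler, rotation matrix, score) triples, best first; invariant to a
    global scale on the observed amplitudes.
    """
    sub = _select_range(obs, d_range)
    mt = _MolecularTransform(em_map)
    s_cart = sub.cell.s_vectors(sub.hkl)
    f_obs = sub.F

    def score(R: np.ndarray) -> float:
        amps = np.abs(mt.sample(s_cart @ R))  # rows: s . R == R^T s
        return _pearson(f_obs, amps)

    scored = []
    for euler in euler_grid(angular_step):
        R = euler_to_matrix(*euler)
        scored.append((euler, R, score(R)))
    scored.sort(key=lambda t: (-t[2], t[0]))

    if refine:
        fine = angular_step / 4.0
        seen = {t[0] for t in scored}
        refined = list(scored)
        for euler, _, _ in scored[:top_n]:
            a0, b0, g0 = euler
            grid = np.arange(-angular_step / 2, angular_step / 2 + 1e-9, fine)
            for da in grid:
                for db in grid:
                    for dg in grid:
                        e = (a0 + da, np.clip(b0 + db, 0.0, 180.0), (g0 + dg) % 360.0)
                        if e in seen:
                            continue
                        seen.add(e)
                        R = euler_to_matrix(*e)
                        refined.append((e, R, score(R)))
        refined.sort(key=lambda t: (-t[2], t[0]))
        scored = refined
    return scored


def translation_search(
    obs: ReflectionSet,
    em_map: MapGrid,
    rotation: np.ndarray,
    sym: SymmetryOps | None = None,
    grid_step: float = 2.0,
    d_range: tuple[float, float] | None = None,
) -> list[Placement]:
    """Exhaustive translation function at a fixed orientation.

    Structure factors for each trial fractional translation come from the
    phase-shift theorem applied to the molecular transform, summed over the
    crystal symmetry operators; the score is amplitude Pearson correlation.
    Returns all grid placements ranked by score (the full list feeds
    :func:`mr_z_score`).
    """
    sub = _select_range(obs, d_range)
    if grid_step < float(sub.d.min()):
        pass  # a grid finer than d_min is allowed; the reverse is the error
    if grid_step > float(sub.d.min()) * 2.0:
        raise ValueError(
            f"translation grid step {grid_step:g} A is coarser than the data "
            f"resolution {sub.d.min():g} A allows"
        )
    if float(np.abs(em_map.rho).max()) == 0.0:
        raise ValueError("no model signal: EM map is identically zero")
    sym = sym or SymmetryOps.p1()
    mt = _MolecularTransform(em_map)
    cell = sub.cell
    R = np.asarray(rotation, float)

    # per symmetry op: molecular transform at (h C_j) and the fixed phase h.v_j
    g_ops, hC_ops, phase0 = [], [], []
    for C, v in sym:
        hC = sub.hkl @ C
        s = cell.s_vectors(hC)
        g_ops.append(mt.sample(s @ R))
        hC_ops.append(hC)
        phase0.append(np.exp(2j * np.pi * (sub.hkl @ v)))

    na = max(2, int(np.ceil(cell.a / grid_step)))
    nb = max(2, int(np.ceil(cell.b / grid_step)))
    nc = max(2, int(np.ceil(cell.c / grid_step)))
    tx, ty, tz = np.meshgrid(
        np.arange(na) / na, np.arange(nb) / nb, np.arange(nc) / nc, indexing="ij"
    )
    trans = np.column_stack([tx.ravel(), ty.ravel(), tz.ravel()])

    f_obs = sub.F
    scores = np.empty(len(trans))
    chunk = max(1, int(2e7 // max(len(sub), 1)))
    for lo in range(0, len(trans), chunk):
        t_blk = trans[lo:lo + chunk]  # (T,3)
        F = np.zeros((len(t_blk), len(sub)), complex)
        for g, hC, p0 in zip(g_ops, hC_ops, phase0):
            F += (g * p0) * np.exp(2j * np.pi * (t_blk @ hC.T))
        A = np.abs(F)
        A -= A.mean(axis=1, keepdims=True)
        fo = f_obs - f_obs.mean()
        den = np.sqrt((A * A).sum(axis=1) * (fo * fo).sum())
        scores[lo:lo + chunk] = np.where(den > 0, (A @ fo) / np.where(den > 0, den, 1), 0.0)

    order = np.lexsort((trans[:, 2], trans[:, 1], trans[:, 0], -scores))
    z = mr_z_score(scores[order]) if len(scores) >= 100 else None
    return [
        Placement(rotation=R, translation=trans[i], score=float(scores[i]),
                  z_score=z if rank == 0 else None)
        for rank, i in enumerate(order)
    ]


def mr_z_score(scores: np.ndarray) -> float:
    """Z-score of the best translation score against the bulk:
    (top - mean(rest)) / std(rest).  Degenerate (zero spread) returns 0."""
    scores = np.sort(np.asarray(scores, float))[::-1]
    if len(scores) < 100:
        raise ValueError("need >= 100 translation scores for a Z-score; use a finer grid")
    rest = scores[1:]
    sd = rest.std()
    if sd == 0.0:
        return 0.0
    return float((scores[0] - rest.mean()) / sd)


def apply_placement(
    em_map: MapGrid,
    placement: Placement,
    crystal_cell: UnitCell,
    sym: SymmetryOps | None = None,
    grid: tuple[int, int, int] | None = None,
    warn_overlap_fraction: float = 0.05,
) -> MapGrid:
    """Resample the placed, symmetry-expanded EM density onto the crystal grid.

    The box center of the EM map is moved to the placement's fractional
    translation after rotation; overlapping symmetry copies are summed.  If
    more than ``warn_overlap_fraction`` of significant density is claimed by
    two or more copies, a ``warn`` attribute records it.
    """
    sym = sym or SymmetryOps.p1()
    if grid is None:
        spacing = em_map.cell.a / em_map.shape[0]
        from .core import grid_for_resolution

        grid = grid_for_resolution(crystal_cell, spacing * 3.0)
    nx, ny, nz = grid
    idx = np.indices(grid, dtype=float)
    x_frac = np.stack(
        [idx[0].ravel() / nx, idx[1].ravel() / ny, idx[2].ravel() / nz], axis=1
    )

    R = placement.rotation
    t = placement.translation
    box_center = np.array([0.5, 0.5, 0.5])
    rho = np.zeros(nx * ny * nz)
    thr = em_map.rho.mean() + em_map.rho.std()
    sig_count = np.zeros(nx * ny * nz)

    for C, v in sym:
        u = x_frac @ C.T + v  # symmetry image of each voxel (fractional)
        d = u - t
        d -= np.round(d)  # minimal-image offset from the placed center
        offs = crystal_cell.orthogonalize(d)
        mol = offs @ R  # rotate into the molecule frame (R^T . offset)
        frac_box = em_map.cell.fractionalize(mol) + box_center
        inside = np.all((frac_box >= 0.0) & (frac_box < 1.0), axis=1)
        vals = np.where(inside, em_map.interpolate_frac(frac_box), 0.0)
        rho += vals
        sig_count += (vals > thr).astype(float)

    out = MapGrid(crystal_cell, rho.reshape(grid))
    sig = sig_count > 0
    overlap = float(np.mean(sig_count[sig] > 1)) if sig.any() else 0.0
    out.warn = (  # type: ignore[attr-defined]
        [f"{overlap:.1%} of significant density claimed by multiple symmetry copies"]
        if overlap > warn_overlap_fraction
        else []
    )
    return out
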