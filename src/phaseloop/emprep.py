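"""Preparation of a low-resolution EM map for molecular replacement.

The four steps mirror how an EM reconstruction is conditioned before it can
serve as a search model against crystal diffraction data: B-factor
sharpening, resolution-dependent FOM weighting derived from an FSC curve,
correction of the microscope magnification error, and placement in a padded
P1 box so the molecular transform is finely sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fftn, ifftn, fftfreq

from .core import MapGrid, UnitCell, grid_for_resolution

__all__ = [
    "ShellCurve",
    "sharpen_map",
    "fom_weight_map",
    "correct_magnification",
    "place_in_p1_box",
    "estimate_diameter",
]


@dataclass
class ShellCurve:
    """Piecewise-constant function of resolution: contiguous shells
    (d_max, d_min] ordered from low to high resolution."""

    d_max: np.ndarray
    d_min: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.d_max = np.asarray(self.d_max, float)
        self.d_min = np.asarray(self.d_min, float)
        self.value = np.asarray(self.value, float)
        if not (len(self.d_max) == len(self.d_min) == len(self.value)):
            raise ValueError("shell arrays differ in length")
        if np.any(self.d_min >= self.d_max):
            raise ValueError("each shell needs d_min < d_max")
        if len(self.d_max) > 1 and np.any(
            np.abs(self.d_max[1:] - self.d_min[:-1]) > 1e-6
        ):
            raise ValueError("shells must be contiguous and ordered low->high resolution")

    @classmethod
    def from_table(cls, d: np.ndarray, value: np.ndarray) -> "ShellCurve":
        """Build shells from per-point (d, value) samples: shell boundaries at
        midpoints in 1/d^3 between consecutive samples."""
        d = np.asarray(d, float)
        value = np.asarray(value, float)
        order = np.argsort(-d)
        d, value = d[order], value[order]
        inv3 = 1.0 / d**3
        mids = 0.5 * (inv3[:-1] + inv3[1:])
        edges = np.concatenate([[0.0], mids, [np.inf]])
        with np.errstate(divide="ignore"):
            d_max = np.where(edges[:-1] > 0, edges[:-1] ** (-1 / 3), np.inf)
            d_min = np.where(edges[1:] > 0, edges[1:] ** (-1 / 3), 0.0)
        return cls(d_max=d_max, d_min=d_min, value=value)

    def lookup(self, d: np.ndarray, high_res_fill: float | None = None) -> np.ndarray:
        """Shell value at resolutions ``d``; raises if a point is uncovered.

        ``high_res_fill``, if given, is used for resolutions beyond the
        curve's high-resolution end instead of raising (an FSC table
        normally stops where the signal does).
        """
        d = np.asarray(d, float)
        out = np.full(d.shape, np.nan)
        for dmx, dmn, v in zip(self.d_max, self.d_min, self.value):
            sel = (d <= dmx) & (d > dmn)
            out[sel] = v
        if high_res_fill is not None:
            beyond = np.isnan(out) & (d <= self.d_min.min())
            out[beyond] = high_res_fill
        if np.any(np.isnan(out)):
            bad = d[np.isnan(out)]
            raise ValueError(
                f"shell curve does not cover resolutions in "
                f"[{bad.min():.3g}, {bad.max():.3g}] A"
            )
        return out


def _s2_grid(map_: MapGrid) -> np.ndarray:
    """|s|^2 on the FFT index grid of the map."""
    nx, ny, nz = map_.shape
    bmat = map_.cell.frac_matrix()  # rows are a*,b*,c*
    h = fftfreq(nx) * nx
    k = fftfreq(ny) * ny
    l = fftfreq(nz) * nz
    hh, kk, ll = np.meshgrid(h, k, l, indexing="ij", sparse=True)
    g = np.array(bmat @ bmat.T)  # reciprocal metric tensor
    return (
        g[0, 0] * hh * hh + g[1, 1] * kk * kk + g[2, 2] * ll * ll
        + 2 * g[0, 1] * hh * kk + 2 * g[0, 2] * hh * ll + 2 * g[1, 2] * kk * ll
    )


def sharpen_map(map_: MapGrid, B_sharpen: float) -> MapGrid:
    """Scale every Fourier coefficient by exp(+B_sharpen * s^2 / 4).

    Positive B sharpens (boosts high resolution), negative B blurs.  The mean
    density (F000 term) is untouched, so sharpening and blurring by the same
    |B| are exact inverses.
    """
    if not np.isfinite(B_sharpen):
        raise ValueError("B_sharpen must be finite")
    if B_sharpen == 0.0:
        return map_.copy()
    coeffs = ifftn(map_.rho, workers=-1)
    scale = np.exp(0.25 * B_sharpen * _s2_grid(map_))
    scale.flat[0] = 1.0
    return MapGrid(map_.cell, np.real(fftn(coeffs * scale, workers=-1)))


def fom_weight_map(map_: MapGrid, fsc: ShellCurve) -> MapGrid:
    """Down-weight each resolution shell by C_ref = sqrt(2*FSC/(1+FSC)).

    Shells with FSC <= 0 are zeroed.  This is the standard conversion from a
    half-map FSC to the expected map-to-truth correlation; it plays the role
    of a per-shell figure of merit on the EM amplitudes.
    """
    if np.any(fsc.value > 1.0) or np.any(fsc.value < -1.0):
        raise ValueError("FSC values must lie in [-1, 1]")
    coeffs = ifftn(map_.rho, workers=-1)
    s2 = _s2_grid(map_)
    with np.errstate(divide="ignore"):
        d = np.where(s2 > 0, 1.0 / np.sqrt(np.where(s2 > 0, s2, 1.0)), np.inf)
    weights = np.ones_like(d)
    flat_d = d.ravel()
    nonzero = flat_d < np.inf
    w = fsc.lookup(flat_d[nonzero], high_res_fill=0.0)
    cref = np.sqrt(np.maximum(0.0, 2.0 * w / (1.0 + np.maximum(w, -0.999))))
    weights.ravel()[nonzero] = np.where(w > 0, cref, 0.0)
    return MapGrid(map_.cell, np.real(fftn(coeffs * weights.reshape(d.shape), workers=-1)))


def correct_magnification(map_: MapGrid, scale: float, bound: float = 0.1) -> MapGrid:
    """Rescale the density by the calibrated magnification factor.

    Features are stretched by ``scale`` about the cell center (a blob of width
    w becomes width scale*w; its centroid relative to the center is
    preserved); values are divided by scale^3 so the integrated density is
    conserved.  Resampling is trilinear.
    """
    if not (1.0 - bound <= scale <= 1.0 + bound):
        raise ValueError(
            f"magnification scale {scale} outside sanity bound "
            f"[{1 - bound}, {1 + bound}] (unit mistake?)"
        )
    if scale == 1.0:
        return map_.copy()
    from scipy.ndimage import map_coordinates

    nx, ny, nz = map_.shape
    center = np.array([nx, ny, nz]) / 2.0
    idx = np.indices(map_.shape, dtype=float)
    coords = [(idx[i] - center[i]) / scale + center[i] for i in range(3)]
    rho = map_coordinates(map_.rho, coords, order=1, mode="grid-wrap")
    return MapGrid(map_.cell, rho / scale**3)


def estimate_diameter(map_: MapGrid, n_sigma: float = 1.0) -> float:
    """Diameter (A) of the smallest sphere containing voxels above
    mean + n_sigma * std.  Used to size the P1 box."""
    thr = map_.rho.mean() + n_sigma * map_.rho.std()
    sel = map_.rho > thr
    if not np.any(sel):
        raise ValueError("no density to box: map has no region above background")
    nx, ny, nz = map_.shape
    ii, jj, kk = np.nonzero(sel)
    frac = np.column_stack([ii / nx, jj / ny, kk / nz])
    cart = map_.cell.orthogonalize(frac)
    centroid = cart.mean(axis=0)
    return 2.0 * float(np.max(np.linalg.norm(cart - centroid, axis=1)))


def place_in_p1_box(
    map_: MapGrid,
    padding_factor: float = 2.0,
    n_sigma: float = 1.0,
    d_min: float | None = None,
) -> tuple[MapGrid, UnitCell]:
    """Center the significant density in a cubic P1 cell with edge
    >= padding_factor * estimated molecular diameter; density outside the
    molecular region is zero.

    Padding below 2x the diameter is refused: the molecular transform would
    be under-sampled and the MR interpolation would alias.
    """
    if padding_factor < 2.0:
        raise ValueError(
            "padding_factor must be >= 2: a box smaller than twice the model "
            "diameter aliases the molecular transform"
        )
    diameter = estimate_diameter(map_, n_sigma)
    edge = padding_factor * diameter
    new_cell = UnitCell(edge, edge, edge)

    # grid fine enough to keep the original sampling (or d_min/3 if given)
    src_spacing = min(
        map_.cell.a / map_.shape[0],
        map_.cell.b / map_.shape[1],
        map_.cell.c / map_.shape[2],
    )
    target = min(src_spacing, d_min / 3.0) if d_min else src_spacing
    n = grid_for_resolution(new_cell, target * 3.0)[0]
    grid = (n, n, n)

    # centroid of significant density, in the source cell
    thr = map_.rho.mean() + n_sigma * map_.rho.std()
    sel = map_.rho > thr
    ii, jj, kk = np.nonzero(sel)
    w = map_.rho[sel]
    src_frac_centroid = np.array(
        [np.average(ii / map_.shape[0], weights=w),
         np.average(jj / map_.shape[1], weights=w),
         np.average(kk / map_.shape[2], weights=w)]
    )

    # sample the source map at positions mapped so its centroid lands at the
    # box center; zero everything beyond the bounding sphere
    idx = np.indices(grid, dtype=float)
    box_frac = np.stack([idx[0] / n, idx[1] / n, idx[2] / n], axis=-1)
    cart = (box_frac - 0.5) * edge  # Cartesian offset from box center (cubic)
    r = np.linalg.norm(cart, axis=-1)
    src_frac = map_.cell.fractionalize(cart.reshape(-1, 3)) + src_frac_centroid
    rho = map_.interpolate_frac(src_frac).reshape(grid)
    rho[r > 0.55 * diameter] = 0.0
    return MapGrid(new_cell, rho), new_cell
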