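"""Real-space density-modification operators and prime-and-switch phasing.

Density modification improves and extends crystallographic phases by forcing
the map to look like a macromolecular map: flat in the solvent region, with
a protein density histogram matching that of a well-phased map at the same
resolution, and with NCS-related copies equal.  The *prime-and-switch*
strategy uses the starting (model-derived) phases only to seed the first
map; after each round of real-space modification the phases are taken
entirely from the modified map ("switch"), never recombined with the
starting phases — this is what removes model bias.  Reliability is tracked
by a sigma-A-derived figure of merit per reflection, and phase extension is
scheduled over shells of increasing resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.fft import fftn, ifftn

from .core import (
    AtomModel,
    MapGrid,
    ReflectionSet,
    SymmetryOps,
    UnitCell,
    grid_for_resolution,
    map_from_structure_factors,
    structure_factors_from_map,
    structure_factors_from_model,
)
from . import sigmaa as _sigmaa

__all__ = [
    "NCSOperator",
    "DensityHistogram",
    "DMConfig",
    "solvent_mask",
    "solvent_flatten",
    "histogram_match",
    "reference_histogram",
    "ncs_average",
    "prime_and_switch",
    "default_extension_schedule",
]


@dataclass
class NCSOperator:
    """Non-crystallographic symmetry operator in Cartesian space.

    Maps a point x (A) of the source copy to ``R @ x + t`` on its NCS mate;
    the source copy is delimited by a spherical mask (center, radius).
    """

    rotation: np.ndarray
    translation: np.ndarray
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        self.center = np.asarray(self.center, float).reshape(3)
        if self.radius <= 0:
            raise ValueError("NCS mask radius must be positive")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("NCS rotation must be orthonormal")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ self.rotation.T + self.translation

    @property
    def is_identity(self) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=1e-9)
            and np.allclose(self.translation, 0.0, atol=1e-9)
        )

    def inverse(self) -> "NCSOperator":
        Rinv = self.rotation.T
        return NCSOperator(
            rotation=Rinv,
            translation=-Rinv @ self.translation,
            center=self.apply(self.center),
            radius=self.radius,
        )

    def to_dict(self) -> dict:
        return {
            "R": self.rotation.ravel().tolist(),
            "t": self.translation.tolist(),
            "center": self.center.tolist(),
            "radius": float(self.radius),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NCSOperator":
        return cls(
            rotation=np.asarray(d["R"], float).reshape(3, 3),
            translation=np.asarray(d["t"], float),
            center=np.asarray(d["center"], float),
            radius=float(d["radius"]),
        )


@dataclass
class DensityHistogram:
    """Normalized histogram of protein-region density values."""

    edges: np.ndarray
    freq: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, float)
        self.freq = np.asarray(self.freq, float)
        if len(self.edges) != len(self.freq) + 1:
            raise ValueError("need len(edges) == len(freq) + 1")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("histogram edges must be increasing")
        if np.any(self.freq < 0):
            raise ValueError("frequencies must be non-negative")
        tot = self.freq.sum()
        if tot <= 0:
            raise ValueError("empty histogram")
        self.freq = self.freq / tot

    @property
    def n_bins(self) -> int:
        return len(self.freq)

    def cdf(self) -> tuple[np.ndarray, np.ndarray]:
        """(edges, cumulative probability at edges)."""
        return self.edges, np.concatenate([[0.0], np.cumsum(self.freq)])

    @classmethod
    def from_values(cls, values: np.ndarray, n_bins: int = 64) -> "DensityHistogram":
        freq, edges = np.histogram(np.asarray(values, float), bins=n_bins)
        return cls(edges=edges, freq=freq.astype(float))


@dataclass
class DMConfig:
    """Knobs of the density-modification / phase-extension engine."""

    solvent_fraction: float = 0.5
    n_inner_cycles: int = 5
    extension_schedule: Sequence[float] = field(default_factory=lambda: [4.87, 2.3])
    mask_smoothing_radius: float = 5.0
    use_solvent: bool = True
    use_histogram: bool = True
    use_ncs: bool = True
    n_sigma_shells: int = 15
    convergence_deg: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.solvent_fraction < 1.0:
            raise ValueError("solvent_fraction must lie in (0,1)")
        sched = list(self.extension_schedule)
        if any(b >= a for a, b in zip(sched, sched[1:])):
            raise ValueError("extension_schedule must be strictly decreasing in d_min")
        self.extension_schedule = sched


def default_extension_schedule(d_start: float, d_min: float, n_steps: int = 4) -> list[float]:
    """n_steps equal shells in 1/d^3 between the starting and final resolution."""
    lo, hi = 1.0 / d_start**3, 1.0 / d_min**3
    return [float((lo + (hi - lo) * i / n_steps) ** (-1.0 / 3.0))
            for i in range(n_steps + 1)]


# --------------------------------------------------------------------------
# real-space operators


def _sphere_smooth(rho: np.ndarray, cell: UnitCell, radius: float) -> np.ndarray:
    """Periodic local mean over a sphere of given radius (FFT convolution with
    the analytic Fourier transform of a solid sphere)."""
    from .emprep import _s2_grid

    s2 = _s2_grid(MapGrid(cell, rho))
    u = 2.0 * np.pi * np.sqrt(s2) * radius
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = np.where(u > 1e-6, 3.0 * (np.sin(u) - u * np.cos(u)) / u**3, 1.0)
    return np.real(fftn(ifftn(rho, workers=-1) * kernel, workers=-1))


def solvent_mask(
    map_: MapGrid,
    solvent_fraction: float,
    smoothing_radius: float = 5.0,
) -> MapGrid:
    """Wang-style solvent mask: the local mean of |rho| over a sphere is
    thresholded at the solvent_fraction quantile.  Returns a 0/1 map
    (1 = protein); the protein fraction equals 1 - solvent_fraction up to
    voxel quantization.  A flat input is flagged ``degenerate``.
    """
    if not 0.0 < solvent_fraction < 1.0:
        raise ValueError("solvent_fraction must lie in (0,1)")
    smooth = _sphere_smooth(np.abs(map_.rho), map_.cell, smoothing_radius)
    thr = np.quantile(smooth, solvent_fraction)
    protein = smooth > thr
    # honor the requested fraction under ties (flat regions)
    deficit = int(round((1.0 - solvent_fraction) * map_.rho.size)) - int(protein.sum())
    degenerate = False
    if deficit > 0:
        ties = np.flatnonzero((smooth == thr).ravel())
        if len(ties):
            degenerate = len(ties) > deficit
            protein.ravel()[ties[:deficit]] = True
    out = MapGrid(map_.cell, protein.astype(float))
    out.degenerate = degenerate  # type: ignore[attr-defined]
    return out


def solvent_flatten(map_: MapGrid, mask: MapGrid) -> MapGrid:
    """Set solvent voxels to the solvent-region mean; protein untouched."""
    protein = mask.rho > 0.5
    rho = map_.rho.copy()
    solvent = ~protein
    if solvent.any():
        rho[solvent] = rho[solvent].mean()
    return MapGrid(map_.cell, rho)


def histogram_match(
    map_: MapGrid,
    target: DensityHistogram,
    protein_mask: MapGrid,
) -> MapGrid:
    """Monotone quantile mapping of protein-region densities onto the target
    histogram; the solvent region is untouched and rank order is preserved."""
    if target.n_bins < 10:
        raise ValueError("target histogram needs at least 10 bins")
    protein = protein_mask.rho > 0.5
    vals = map_.rho[protein]
    n = len(vals)
    if n == 0:
        return map_.copy()
    order = np.argsort(vals, kind="stable")
    p = (np.arange(n) + 0.5) / n
    edges, cdf = target.cdf()
    # inverse target CDF (strictly increasing segments only)
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    mapped_sorted = np.interp(p, cdf[keep], edges[keep])
    new_vals = np.empty(n)
    new_vals[order] = mapped_sorted
    rho = map_.rho.copy()
    rho[protein] = new_vals
    return MapGrid(map_.cell, rho)


def reference_histogram(
    model: AtomModel,
    cell: UnitCell,
    grid: tuple[int, int, int] | None = None,
    d_min: float = 3.0,
    sym: SymmetryOps | None = None,
    n_bins: int = 64,
    atom_radius: float = 2.5,
    solvent_fraction: float | None = None,
    mask_smoothing_radius: float = 5.0,
) -> DensityHistogram:
    """Target protein-density histogram from a model's map at the working
    resolution.

    When ``solvent_fraction`` is given, the protein region is defined by the
    same Wang mask that density modification will use (same fraction and
    smoothing radius), so the target statistics refer to the same kind of
    region they will be imposed on; otherwise the region is the tight
    ``atom_radius`` envelope of the atoms.
    """
    grid = grid or grid_for_resolution(cell, d_min)
    sf = structure_factors_from_model(model, cell, sym, d_min=d_min)
    m = map_from_structure_factors(sf, cell, grid)
    if solvent_fraction is not None:
        protein = solvent_mask(m, solvent_fraction, mask_smoothing_radius).rho > 0.5
    else:
        protein = _atom_region_mask(model, cell, grid, atom_radius, sym)
    return DensityHistogram.from_values(m.rho[protein], n_bins=n_bins)


def reference_histogram_provider(
    model: AtomModel,
    cell: UnitCell,
    config: "DMConfig",
    grid: tuple[int, int, int] | None = None,
    sym: SymmetryOps | None = None,
) -> Callable[[float], DensityHistogram]:
    """Cached d_min -> histogram callable for :func:`prime_and_switch`,
    consistent with the config's Wang-mask parameters."""
    cache: dict[float, DensityHistogram] = {}

    def provider(d_min: float) -> DensityHistogram:
        key = round(float(d_min), 6)
        if key not in cache:
            cache[key] = reference_histogram(
                model, cell, grid, d_min=key, sym=sym,
                solvent_fraction=config.solvent_fraction,
                mask_smoothing_radius=config.mask_smoothing_radius,
            )
        return cache[key]

    return provider


def _atom_region_mask(
    model: AtomModel,
    cell: UnitCell,
    grid: tuple[int, int, int],
    radius: float,
    sym: SymmetryOps | None = None,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean voxel mask within ``radius`` A of any (symmetry-expanded) atom."""
    from scipy.spatial import cKDTree

    nx, ny, nz = grid
    frac = cell.fractionalize(model.xyz if subset is None else model.xyz[subset])
    pts = [frac]
    for R, t in (sym or SymmetryOps.p1()):
        if np.allclose(R, np.eye(3)) and np.allclose(t, 0):
            continue
        pts.append(frac @ R.T + t)
    frac_all = np.mod(np.vstack(pts), 1.0)

    if cell.is_orthogonal():
        cart = frac_all * np.array([cell.a, cell.b, cell.c])
        tree = cKDTree(cart, boxsize=[cell.a, cell.b, cell.c])
        ii, jj, kk = np.meshgrid(
            np.arange(nx) * cell.a / nx,
            np.arange(ny) * cell.b / ny,
            np.arange(nz) * cell.c / nz,
            indexing="ij",
        )
        vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
        d, _ = tree.query(vox, workers=-1)
        return (d <= radius).reshape(grid)

    # general cell: expand periodic images explicitly
    shifts = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1])).T.reshape(-1, 3)
    imgs = (frac_all[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    cart = cell.orthogonalize(imgs)
    tree = cKDTree(cart)
    ii, jj, kk = np.meshgrid(
        np.arange(nx) / nx, np.arange(ny) / ny, np.arange(nz) / nz, indexing="ij"
    )
    vox = cell.orthogonalize(np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]))
    d, _ = tree.query(vox, workers=-1)
    return (d <= radius).reshape(grid)


def ncs_average(map_: MapGrid, ops: Sequence[NCSOperator],
                edge_taper: float = 3.0) -> MapGrid:
    """Average each operator's spherical source region with its NCS image.

    For every voxel x inside an operator's mask, the output density blends
    toward the mean of rho(x) and rho(op(x)) (trilinear, periodic); the
    blend weight tapers cosine-smoothly to zero over the outer ``edge_taper``
    Angstroms of the sphere, so the mask edge does not scatter phase in
    reciprocal space.  Voxels outside all masks are untouched, identity
    operators contribute nothing, and all operators read from the input map,
    so the result does not depend on operator order.
    """
    real_ops = [op for op in ops if not op.is_identity]
    if not real_ops:
        return map_.copy()
    nx, ny, nz = map_.shape
    cell = map_.cell
    idx_grid = np.indices(map_.shape).reshape(3, -1).T
    frac_all = idx_grid / np.array([nx, ny, nz])

    acc = np.zeros(map_.rho.size)
    wsum = np.zeros(map_.rho.size)
    for op in real_ops:
        cfrac = np.mod(cell.fractionalize(op.center), 1.0)
        dfrac = frac_all - cfrac
        dfrac -= np.round(dfrac)  # minimal image
        r = np.linalg.norm(cell.orthogonalize(dfrac), axis=1)
        sel = r <= op.radius
        if not sel.any():
            raise ValueError("NCS mask covers no voxels inside the cell")
        taper = min(edge_taper, 0.5 * op.radius)
        w = np.clip((op.radius - r[sel]) / max(taper, 1e-6), 0.0, 1.0)
        w = 0.5 * (1.0 - np.cos(np.pi * w))  # cosine feather
        x = cell.orthogonalize(dfrac[sel] + cfrac)
        images = op.apply(x)
        img_vals = map_.interpolate_frac(cell.fractionalize(images))
        flat = np.flatnonzero(sel)
        acc[flat] += w * 0.5 * (map_.rho.ravel()[flat] + img_vals)
        wsum[flat] += w
    blend = np.minimum(wsum, 1.0)
    avg = np.where(wsum > 0, acc / np.maximum(wsum, 1e-300), 0.0)
    rho = (1.0 - blend) * map_.rho.ravel() + blend * avg
    return MapGrid(cell, rho.reshape(map_.shape))


# --------------------------------------------------------------------------
# prime-and-switch phase improvement / extension


def _modify_map(
    m: MapGrid,
    config: DMConfig,
    target_hist: DensityHistogram | None,
    ncs_ops: Sequence[NCSOperator] | None,
) -> MapGrid:
    if config.use_ncs and ncs_ops:
        m = ncs_average(m, ncs_ops)
    mask = None
    if config.use_solvent or config.use_histogram:
        mask = solvent_mask(m, config.solvent_fraction, config.mask_smoothing_radius)
    if config.use_solvent:
        m = solvent_flatten(m, mask)
    if config.use_histogram and target_hist is not None:
        m = histogram_match(m, target_hist, mask)
    return m


def prime_and_switch(
    obs: ReflectionSet,
    start_phases: ReflectionSet,
    config: DMConfig,
    reference_hist: DensityHistogram | Callable[[float], DensityHistogram] | None = None,
    ncs_ops: Sequence[NCSOperator] | None = None,
    grid: tuple[int, int, int] | None = None,
) -> ReflectionSet:
    """Prime-and-switch density modification with scheduled phase extension.

    The starting phases only seed the first map.  Each inner cycle
    synthesizes a FOM-weighted map from the current phases and observed
    amplitudes, applies the enabled real-space operators, back-transforms,
    and *switches* to the modified map's phases (the input phases are never
    recombined — the model-bias-removal contract).  New figures of merit come
    from shellwise sigma-A between observed and modified-map amplitudes.
    When the schedule advances, newly included reflections enter with the
    modified-map phase and their shell's FOM.

    Returns phases+FOMs for every observed reflection to the schedule's last
    d_min.
    """
    if start_phases.phi is None:
        raise ValueError("start_phases must carry phases")
    sched = [float(d) for d in config.extension_schedule]
    d_obs_min = float(obs.d.min())
    if sched[-1] < 0.99 * d_obs_min:
        raise ValueError(
            f"extension schedule reaches {sched[-1]:g} A but observed data stop "
            f"at {d_obs_min:g} A"
        )
    cell = obs.cell
    grid = grid or grid_for_resolution(cell, sched[-1])

    work = obs.select(obs.d >= sched[-1] - 1e-9).sort_by_resolution()
    d_work = work.d
    phi = np.full(len(work), np.nan)
    fom = np.zeros(len(work))
    ia, ib = work.match(start_phases)
    phi[ia] = start_phases.phi[ib]
    fom[ia] = start_phases.fom[ib] if start_phases.fom is not None else 1.0
    if not np.any(~np.isnan(phi[d_work >= sched[0]])):
        raise ValueError("start_phases do not cover the lowest extension shell")

    e_obs_all = _sigmaa.normalize_amplitudes(work, config.n_sigma_shells)

    # One real-space modification pass per inner cycle; the extension
    # schedule advances one shell per pass until exhausted, after which the
    # remaining passes settle at the final resolution.  The loop always
    # reaches the schedule's last d_min even if n_inner_cycles is smaller
    # than the number of shells.
    steps = sched[1:] if len(sched) > 1 else [sched[0]]
    n_iter = max(config.n_inner_cycles, len(steps))
    d_seq = steps + [steps[-1]] * (n_iter - len(steps))
    for it, d_cur in enumerate(d_seq):
        active = d_work >= d_cur - 1e-9
        have = active & ~np.isnan(phi)
        src = work.select(have).copy(phi=phi[have], fom=np.clip(fom[have], 0.0, 1.0))
        m = map_from_structure_factors(src, cell, grid, use_fom_weights=True)
        target = (
            reference_hist(d_cur) if callable(reference_hist) else reference_hist
        )
        m = _modify_map(m, config, target, ncs_ops)

        # back-transform and SWITCH for every active reflection
        coeffs = ifftn(m.rho, workers=-1) * cell.volume
        nx, ny, nz = grid
        sub = work.hkl[active]
        vals = coeffs[sub[:, 0] % nx, sub[:, 1] % ny, sub[:, 2] % nz]
        new_phi = np.degrees(np.angle(vals)) % 360.0
        old = phi[active]
        # a vanished coefficient carries no phase information: keep the old one
        dead = np.abs(vals) < 1e-12 * max(1.0, np.abs(vals).max())
        new_phi = np.where(dead & ~np.isnan(old), old, new_phi)
        delta = np.abs((new_phi - old + 180.0) % 360.0 - 180.0)
        phi[active] = new_phi

        # sigma-A FOM between observed and modified-map amplitudes
        mod_set = work.select(active).copy(F=np.abs(vals), phi=None, fom=None)
        e_calc = _sigmaa.normalize_amplitudes(mod_set, config.n_sigma_shells)
        sigA = _sigmaa.estimate_sigma_a(
            e_obs_all.select(active), e_calc, config.n_sigma_shells
        )
        fom[active] = _sigmaa.fom_from_sigma_a(
            sigA, e_obs_all.F[active], e_calc.F, d_work[active]
        )
        # convergence can only be declared once fully extended
        if it >= len(steps) and np.nanmean(delta) < config.convergence_deg:
            break

    keep = ~np.isnan(phi)
    return work.select(keep).copy(phi=phi[keep], fom=np.clip(fom[keep], 0.0, 0.9999))
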