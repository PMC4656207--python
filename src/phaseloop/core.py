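"""Unit-cell geometry, reciprocal-space containers and map<->structure-factor
transforms.

Conventions used throughout the package
---------------------------------------
* The structure factor of density ``rho`` sampled on a unit-cell grid is

      F(h) = V * <rho(x) * exp(+2*pi*i h.x)>_cell

  with ``x`` fractional, i.e. the *positive* exponent convention; the map
  synthesis inverse uses ``exp(-2*pi*i h.x)``.
* F(000) is excluded everywhere, so synthesized maps are zero-mean.
* Unique reflections are stored on the Friedel hemisphere
  ``(h>0) or (h==0 and k>0) or (h==0 and k==0 and l>0)``.
* Fractional coordinates are the internal standard; the orthogonalization
  matrix places the cell edge ``a`` along Cartesian x.
* Phases are degrees in [0, 360) at the API surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.fft import fftn, ifftn, next_fast_len

__all__ = [
    "UnitCell",
    "SymmetryOps",
    "ReflectionSet",
    "MapGrid",
    "AtomModel",
    "FORM_FACTORS",
    "resolution_of",
    "structure_factors_from_map",
    "map_from_structure_factors",
    "structure_factors_from_model",
    "gaussian_density_from_model",
    "grid_for_resolution",
]

DEG = 180.0 / np.pi


# --------------------------------------------------------------------------
# unit cell


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell; lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180)")
        if np.linalg.det(self.orth_matrix()) <= 0:
            raise ValueError("cell metric is not positive definite")

    def orth_matrix(self) -> np.ndarray:
        """Fractional -> Cartesian matrix, columns are the cell vectors (a||x)."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v = np.sqrt(max(0.0, 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg))
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    def frac_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orth_matrix())

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.orth_matrix()))

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, float) @ self.orth_matrix().T

    def fractionalize(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, float) @ self.frac_matrix().T

    def s_vectors(self, hkl: np.ndarray) -> np.ndarray:
        """Reciprocal-lattice vectors (A^-1) for Miller indices, rows."""
        bmat = self.frac_matrix()  # rows of frac_matrix are a*,b*,c*
        return np.asarray(hkl, float) @ bmat

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        s = np.linalg.norm(self.s_vectors(hkl), axis=-1)
        with np.errstate(divide="ignore"):
            return np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), np.inf)

    def is_orthogonal(self, tol: float = 1e-9) -> bool:
        return all(abs(x - 90.0) < tol for x in (self.alpha, self.beta, self.gamma))


def resolution_of(hkl: Sequence[int] | np.ndarray, cell: UnitCell) -> float | np.ndarray:
    """d-spacing in Angstrom of one Miller index (or an (N,3) array of them).

    Raises ``ValueError`` for (0,0,0): F000 has no resolution.
    """
    arr = np.atleast_2d(np.asarray(hkl, int))
    if np.any(~arr.any(axis=1)):
        raise ValueError("F000 has no resolution")
    d = cell.d_spacing(arr)
    return float(d[0]) if np.asarray(hkl).ndim == 1 else d


# --------------------------------------------------------------------------
# symmetry


class SymmetryOps:
    """Explicit space-group operators ``x -> R x + t`` on fractional coordinates.

    The identity is always present and stored first.  Operators are supplied
    explicitly (no space-group table lookup); :meth:`p1` and :meth:`p21_b`
    cover the toy cases used throughout.
    """

    def __init__(self, ops: Iterable[tuple[np.ndarray, np.ndarray]] | None = None):
        mats: list[tuple[np.ndarray, np.ndarray]] = []
        seen: set[tuple] = set()

        def add(R: np.ndarray, t: np.ndarray) -> None:
            R = np.asarray(R, float).reshape(3, 3)
            t = np.mod(np.asarray(t, float).reshape(3), 1.0)
            key = (tuple(np.round(R.ravel(), 9)), tuple(np.round(t, 9)))
            if key not in seen:
                seen.add(key)
                mats.append((R, t))

        add(np.eye(3), np.zeros(3))
        for R, t in ops or []:
            add(R, t)
        self._ops = mats

    @classmethod
    def p1(cls) -> "SymmetryOps":
        return cls()

    @classmethod
    def p21_b(cls) -> "SymmetryOps":
        """P2_1 with the screw axis along b: (x,y,z) -> (-x, y+1/2, -z)."""
        return cls([(np.diag([-1.0, 1.0, -1.0]), np.array([0.0, 0.5, 0.0]))])

    def __len__(self) -> int:
        return len(self._ops)

    def __iter__(self):
        return iter(self._ops)

    def __getitem__(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        return self._ops[i]

    @property
    def rotations(self) -> np.ndarray:
        return np.stack([R for R, _ in self._ops])

    @property
    def translations(self) -> np.ndarray:
        return np.stack([t for _, t in self._ops])

    def is_centric(self, hkl: np.ndarray) -> np.ndarray:
        """Flag reflections with h.R = -h for some operator."""
        hkl = np.atleast_2d(np.asarray(hkl, float))
        out = np.zeros(len(hkl), bool)
        for R, _ in self._ops:
            out |= np.all(np.abs(hkl @ R + hkl) < 1e-9, axis=1)
        return out


# --------------------------------------------------------------------------
# reflections


def hemisphere_mask(hkl: np.ndarray) -> np.ndarray:
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    return (h > 0) | ((h == 0) & (k > 0)) | ((h == 0) & (k == 0) & (l > 0))


@dataclass
class ReflectionSet:
    """Miller-indexed amplitudes with optional uncertainties, phases and FOMs.

    ``hkl`` is an (N,3) int array restricted to the Friedel hemisphere;
    amplitudes are non-negative; phases are degrees in [0,360); figures of
    merit lie in [0,1].
    """

    cell: UnitCell
    hkl: np.ndarray
    F: np.ndarray
    sigF: np.ndarray | None = None
    phi: np.ndarray | None = None
    fom: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, int).reshape(-1, 3)
        self.F = np.asarray(self.F, float).reshape(-1)
        n = len(self.hkl)
        if len(self.F) != n:
            raise ValueError("hkl and F lengths differ")
        for name in ("sigF", "phi", "fom"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, float).reshape(-1)
                if len(v) != n:
                    raise ValueError(f"{name} length differs from hkl")
                setattr(self, name, v)
        if n and np.any(~self.hkl.any(axis=1)):
            raise ValueError("F000 is excluded from ReflectionSet")
        if np.any(self.F < 0):
            raise ValueError("amplitudes must be non-negative")
        if self.phi is not None:
            self.phi = np.mod(self.phi, 360.0)
        if self.fom is not None and (np.any(self.fom < 0) or np.any(self.fom > 1)):
            raise ValueError("fom must lie in [0,1]")
        key = self.hkl @ np.array([1_000_000, 1_000, 1]) if n else np.empty(0)
        if n and len(np.unique(key)) != n:
            raise ValueError("duplicated (h,k,l) in ReflectionSet")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def d(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    @property
    def s2(self) -> np.ndarray:
        """|s|^2 = 1/d^2 per reflection."""
        return np.sum(self.cell.s_vectors(self.hkl) ** 2, axis=1)

    def copy(self, **changes) -> "ReflectionSet":
        base = dict(
            cell=self.cell,
            hkl=self.hkl.copy(),
            F=self.F.copy(),
            sigF=None if self.sigF is None else self.sigF.copy(),
            phi=None if self.phi is None else self.phi.copy(),
            fom=None if self.fom is None else self.fom.copy(),
        )
        base.update(changes)
        return ReflectionSet(**base)

    def select(self, mask: np.ndarray) -> "ReflectionSet":
        return ReflectionSet(
            cell=self.cell,
            hkl=self.hkl[mask],
            F=self.F[mask],
            sigF=None if self.sigF is None else self.sigF[mask],
            phi=None if self.phi is None else self.phi[mask],
            fom=None if self.fom is None else self.fom[mask],
        )

    def _key(self) -> np.ndarray:
        off = 512
        return ((self.hkl[:, 0] + off) * 1024 + (self.hkl[:, 1] + off)) * 1024 + (
            self.hkl[:, 2] + off
        )

    def match(self, other: "ReflectionSet") -> tuple[np.ndarray, np.ndarray]:
        """Index arrays (ia, ib) of reflections common to self and other."""
        ka, kb = self._key(), other._key()
        common, ia, ib = np.intersect1d(ka, kb, return_indices=True)
        return ia, ib

    def complex_F(self) -> np.ndarray:
        if self.phi is None:
            raise ValueError("reflection set has no phases")
        return self.F * np.exp(1j * np.radians(self.phi))

    def sort_by_resolution(self) -> "ReflectionSet":
        order = np.lexsort((self.hkl[:, 2], self.hkl[:, 1], self.hkl[:, 0], -self.d))
        return self.select(order)


# --------------------------------------------------------------------------
# maps


@dataclass
class MapGrid:
    """Real-space density sampled on a unit-cell grid.

    ``rho[i,j,k]`` is the density at fractional position (i/nx, j/ny, k/nz);
    the x index runs fastest in memory terms of crystallographic axis order.
    """

    cell: UnitCell
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, float)
        if self.rho.ndim != 3 or min(self.rho.shape) < 2:
            raise ValueError("rho must be a 3-D grid with all divisions >= 2")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.rho.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return self.cell.volume / self.rho.size

    def copy(self) -> "MapGrid":
        return MapGrid(self.cell, self.rho.copy())

    def voxel_frac_coords(self) -> np.ndarray:
        """(N,3) fractional coordinates of every voxel, C order."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx) / nx, np.arange(ny) / ny, np.arange(nz) / nz, indexing="ij"
        )
        return np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)

    def interpolate_frac(self, frac: np.ndarray) -> np.ndarray:
        """Trilinear, periodic interpolation at fractional coordinates."""
        from scipy.ndimage import map_coordinates

        frac = np.atleast_2d(np.asarray(frac, float))
        idx = (frac * np.array(self.shape)).T
        return map_coordinates(self.rho, idx, order=1, mode="grid-wrap")

    def correlation(self, other: "MapGrid", mask: np.ndarray | None = None) -> float:
        a, b = self.rho, other.rho
        if a.shape != b.shape:
            raise ValueError("grids differ in shape")
        if mask is not None:
            a, b = a[mask], b[mask]
        a = a - a.mean()
        b = b - b.mean()
        den = np.sqrt((a * a).sum() * (b * b).sum())
        return float((a * b).sum() / den) if den > 0 else 0.0


def grid_for_resolution(cell: UnitCell, d_min: float, factor: float = 3.0) -> tuple[int, int, int]:
    """FFT-friendly grid with spacing <= d_min/factor along every axis.

    The default oversampling factor 3 (finer than the Shannon limit of 2)
    suppresses aliasing in the density-modification cycles.
    """
    return tuple(
        next_fast_len(int(np.ceil(length * factor / d_min)), real=False)
        for length in (cell.a, cell.b, cell.c)
    )


def _unique_hkl_to_dmin(cell: UnitCell, d_min: float) -> np.ndarray:
    """All hemisphere Miller indices with d >= d_min, sorted low->high resolution."""
    smax = 1.0 / d_min
    # |h| = |s . a_vec| <= smax * a, and likewise for k, l (valid for any cell)
    hmax = int(np.floor(smax * cell.a))
    kmax = int(np.floor(smax * cell.b))
    lmax = int(np.floor(smax * cell.c))
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[hemisphere_mask(hkl)]
    d = cell.d_spacing(hkl)
    hkl = hkl[d >= d_min]
    d = cell.d_spacing(hkl)
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0], -d))
    return hkl[order]


def structure_factors_from_map(map_: MapGrid, d_min: float) -> ReflectionSet:
    """Inverse-FT structure factors of a density map to resolution ``d_min``.

    One record per unique hemisphere (h,k,l) with d >= d_min; F(000) excluded.
    Raises if the grid is coarser than d_min/3 along any axis.
    """
    cell = map_.cell
    need = grid_for_resolution(cell, d_min)
    for n, n_need, axis in zip(map_.shape, need, "abc"):
        if n < int(np.ceil({"a": cell.a, "b": cell.b, "c": cell.c}[axis] * 3.0 / d_min)):
            raise ValueError(
                f"grid too coarse along {axis} for d_min={d_min:g} A: "
                f"have {n} divisions, need >= {n_need}"
            )
    # F(h) = V * mean(rho * exp(+2 pi i h.x)) == V * ifftn(rho)[h]
    coeffs = ifftn(map_.rho, workers=-1) * cell.volume
    hkl = _unique_hkl_to_dmin(cell, d_min)
    nx, ny, nz = map_.shape
    vals = coeffs[hkl[:, 0] % nx, hkl[:, 1] % ny, hkl[:, 2] % nz]
    return ReflectionSet(
        cell=cell,
        hkl=hkl,
        F=np.abs(vals),
        phi=np.degrees(np.angle(vals)) % 360.0,
    )


def map_from_structure_factors(
    refl: ReflectionSet,
    cell: UnitCell | None = None,
    grid: tuple[int, int, int] | None = None,
    use_fom_weights: bool = False,
) -> MapGrid:
    """Fourier synthesis of a (optionally FOM-weighted) density map.

    Coefficients are ``F*exp(i*phi)`` or ``m*F*exp(i*phi)``; Friedel mates are
    completed by conjugation, so the output is real.  The map is zero-mean
    because F(000) is never stored.
    """
    if refl.phi is None:
        raise ValueError("cannot synthesize a map without phases")
    if use_fom_weights and refl.fom is None:
        raise ValueError("use_fom_weights requires figures of merit")
    cell = cell or refl.cell
    if grid is None:
        d_min = float(refl.d.min()) if len(refl) else 10.0
        grid = grid_for_resolution(cell, d_min)
    nx, ny, nz = grid
    vals = refl.complex_F()
    if use_fom_weights:
        vals = vals * refl.fom
    cgrid = np.zeros(grid, complex)
    idx = (refl.hkl[:, 0] % nx, refl.hkl[:, 1] % ny, refl.hkl[:, 2] % nz)
    cgrid[idx] = vals
    nidx = ((-refl.hkl[:, 0]) % nx, (-refl.hkl[:, 1]) % ny, (-refl.hkl[:, 2]) % nz)
    cgrid[nidx] = np.conj(vals)
    # rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x) == fftn(F_grid)/V
    rho = np.real(fftn(cgrid, workers=-1)) / cell.volume
    return MapGrid(cell, rho)


# --------------------------------------------------------------------------
# atomic models

# Single-Gaussian form factors f(s) = a * exp(-b * s^2 / 4), s = 1/d.
# Coarse one-term fits adequate for the >= 2 A toy scale of this package;
# 'X' is the generic dummy scatterer used for auto-built pseudo-atoms.
FORM_FACTORS: dict[str, tuple[float, float]] = {
    "C": (6.0, 13.0),
    "N": (7.0, 11.0),
    "O": (8.0, 9.0),
    "S": (16.0, 7.0),
    "X": (6.0, 13.0),
}

MAIN_CHAIN = "main"
SIDE_CHAIN = "side"


@dataclass
class AtomModel:
    """Point-atom model: Cartesian positions (A), B-factors (A^2), occupancies,
    chain ids, residue numbers and a main-/side-chain role flag."""

    element: list[str]
    xyz: np.ndarray
    B: np.ndarray
    occ: np.ndarray
    chain: list[str] = field(default_factory=list)
    resnum: np.ndarray | None = None
    role: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, float).reshape(-1, 3)
        n = len(self.xyz)
        self.element = list(self.element)
        self.B = np.asarray(self.B, float).reshape(-1)
        self.occ = np.asarray(self.occ, float).reshape(-1)
        if not self.chain:
            self.chain = ["A"] * n
        if self.resnum is None:
            self.resnum = np.arange(1, n + 1)
        self.resnum = np.asarray(self.resnum, int).reshape(-1)
        if not self.role:
            self.role = [MAIN_CHAIN] * n
        if not (len(self.element) == len(self.B) == len(self.occ) == n):
            raise ValueError("inconsistent atom array lengths")
        if np.any(self.B <= 0):
            raise ValueError("B-factors must be positive")
        if np.any((self.occ <= 0) | (self.occ > 1)):
            raise ValueError("occupancies must lie in (0,1]")

    def __len__(self) -> int:
        return len(self.xyz)

    def select(self, mask: np.ndarray) -> "AtomModel":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return AtomModel(
            element=[self.element[i] for i in idx],
            xyz=self.xyz[idx],
            B=self.B[idx],
            occ=self.occ[idx],
            chain=[self.chain[i] for i in idx],
            resnum=self.resnum[idx],
            role=[self.role[i] for i in idx],
        )

    def role_mask(self, role: str) -> np.ndarray:
        return np.array([r == role for r in self.role])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "AtomModel":
        out = self.select(np.arange(len(self)))
        out.xyz = self.xyz @ np.asarray(R).T + np.asarray(t)
        return out


def _form_factor_params(elements: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    a = np.empty(len(elements))
    b = np.empty(len(elements))
    warnings: list[str] = []
    for i, e in enumerate(elements):
        key = e.strip().upper()
        if key not in FORM_FACTORS:
            warnings.append(f"unknown element {e!r}: using dummy scatterer")
            key = "X"
        a[i], b[i] = FORM_FACTORS[key]
    return a, b, warnings


def structure_factors_from_model(
    model: AtomModel,
    cell: UnitCell,
    sym: SymmetryOps | None = None,
    d_min: float = 3.0,
    hkl: np.ndarray | None = None,
    chunk: int = 4_000_000,
) -> ReflectionSet:
    """Direct-summation structure factors of an atomic model.

    F(h) = sum_sym sum_atoms occ * f(s) * exp(-B s^2/4) * exp(2 pi i h.x_frac)

    with a single-Gaussian form factor per element.  This is the package's
    slow, transparent oracle; the FFT path is validated against it.  A list
    of warning strings (unknown elements) is attached as ``warn`` on the
    returned set.
    """
    if len(model) == 0:
        raise ValueError("model has no atoms")
    sym = sym or SymmetryOps.p1()
    if hkl is None:
        hkl = _unique_hkl_to_dmin(cell, d_min)
    hkl = np.asarray(hkl, int).reshape(-1, 3)
    s2 = np.sum(cell.s_vectors(hkl) ** 2, axis=1)
    a, b, warnings = _form_factor_params(model.element)
    frac = cell.fractionalize(model.xyz)

    F = np.zeros(len(hkl), complex)
    # amplitude envelope per (reflection, atom): occ * a * exp(-(B+b) s^2/4)
    n_at = len(model)
    step = max(1, chunk // max(n_at, 1))
    for R, t in sym:
        xs = frac @ R.T + t
        for lo in range(0, len(hkl), step):
            sl = slice(lo, lo + step)
            phase = np.exp(2j * np.pi * (hkl[sl] @ xs.T))
            env = model.occ * a * np.exp(-0.25 * np.outer(s2[sl], model.B + b))
            F[sl] += np.einsum("ij,ij->i", env, phase)

    out = ReflectionSet(
        cell=cell,
        hkl=hkl,
        F=np.abs(F),
        phi=np.degrees(np.angle(F)) % 360.0,
    )
    out.warn = warnings  # type: ignore[attr-defined]
    return out


def gaussian_density_from_model(
    model: AtomModel,
    cell: UnitCell,
    grid: tuple[int, int, int],
    sym: SymmetryOps | None = None,
    cutoff_sigma: float = 4.5,
) -> MapGrid:
    """Rasterize the model's Gaussian atoms onto a periodic grid.

    Each atom contributes ``occ * a * (4 pi / (B+b))^{3/2} exp(-4 pi^2 r^2/(B+b))``,
    the exact real-space pair of the single-Gaussian form factor, so the FFT of
    this map reproduces :func:`structure_factors_from_model` up to sampling
    error.  Used by the test oracle and the synthetic EM-map generator.
    """
    if len(model) == 0:
        raise ValueError("model has no atoms")
    sym = sym or SymmetryOps.p1()
    nx, ny, nz = grid
    rho = np.zeros(grid)
    a, b, _ = _form_factor_params(model.element)
    frac_all = cell.fractionalize(model.xyz)
    orth = cell.orth_matrix()
    spacing = np.array([cell.a / nx, cell.b / ny, cell.c / nz])

    for R, t in sym:
        frac = frac_all @ R.T + t
        for i in range(len(model)):
            beta = model.B[i] + b[i]  # A^2
            sigma = np.sqrt(beta / (8.0 * np.pi**2))  # real-space std dev, A
            peak = model.occ[i] * a[i] * (4.0 * np.pi / beta) ** 1.5
            reach = cutoff_sigma * sigma
            nrad = np.maximum(1, np.ceil(reach / spacing).astype(int))
            center = frac[i] * np.array([nx, ny, nz])
            i0 = np.floor(center).astype(int)
            ox = np.arange(i0[0] - nrad[0], i0[0] + nrad[0] + 1)
            oy = np.arange(i0[1] - nrad[1], i0[1] + nrad[1] + 1)
            oz = np.arange(i0[2] - nrad[2], i0[2] + nrad[2] + 1)
            fx = ox / nx - frac[i, 0]
            fy = oy / ny - frac[i, 1]
            fz = oz / nz - frac[i, 2]
            dfrac = np.stack(
                np.meshgrid(fx, fy, fz, indexing="ij"), axis=-1
            ).reshape(-1, 3)
            r2 = np.sum((dfrac @ orth.T) ** 2, axis=1)
            vals = peak * np.exp(-4.0 * np.pi**2 * r2 / beta)
            np.add.at(
                rho,
                (
                    np.repeat(ox % nx, len(oy) * len(oz)),
                    np.tile(np.repeat(oy % ny, len(oz)), len(ox)),
                    np.tile(oz % nz, len(ox) * len(oy)),
                ),
                vals.reshape(-1),
            )
    rho -= rho.mean()  # F000 excluded by convention
    return MapGrid(cell, rho)
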