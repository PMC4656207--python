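"""Self-contained synthetic analog of the EM-seeded phase-extension problem.

The generator builds a compact two-copy pseudo-protein (a toroidal-helix
C-alpha trace with one side-chain pseudo-atom per residue, duplicated by an
exact proper two-fold NCS operator), then derives from it everything the
pipeline consumes: high-resolution "observed" amplitudes with multiplicative
noise, ground-truth phases for scoring, a low-resolution phase set standing
in for the molecular-replacement-placed EM map (truth phases degraded by
wrapped-Gaussian noise), and the exact NCS operators.

Defaults mirror the study conditions this package emulates: two NCS copies,
a 4.87 A EM-like start, 2.3 A observed amplitudes at 5% amplitude noise,
45 degree EM phase noise, and a P1 cell with edges in the 60-80 A range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AtomModel,
    MAIN_CHAIN,
    SIDE_CHAIN,
    MapGrid,
    ReflectionSet,
    SymmetryOps,
    UnitCell,
    grid_for_resolution,
    map_from_structure_factors,
    structure_factors_from_model,
)
from .densmod import DMConfig, NCSOperator, default_extension_schedule

__all__ = [
    "make_toy_structure",
    "simulate_observed",
    "simulate_em_map",
    "standard_scenario",
    "ScenarioBundle",
]

EM_RESOLUTION = 4.87  # A
XRAY_RESOLUTION = 2.3  # A
DEFAULT_CELL = (61.0, 64.0, 67.0)  # P1, edges in the 60-80 A band
DEFAULT_N_RESIDUES = 60  # per NCS copy
DEFAULT_AMP_NOISE = 0.05
DEFAULT_PHASE_NOISE_DEG = 45.0


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _axis_angle_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    th = np.radians(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _toroidal_trace(n_points: int, R_major: float, r_tube: float,
                    spacing: float = 3.8) -> np.ndarray:
    """Points every ``spacing`` A along a toroidal helix (self-avoiding by
    construction: adjacent tube windings stay > 2 A apart)."""
    # winding rate chosen so the curve's speed yields the requested arc length
    n_wind = np.sqrt(max((spacing * n_points / (2 * np.pi)) ** 2 - R_major**2, 1.0)) / r_tube
    t_dense = np.linspace(0.0, 2.2 * np.pi, 200 * n_points)
    w = n_wind * t_dense
    pts = np.column_stack([
        (R_major + r_tube * np.cos(w)) * np.cos(t_dense),
        (R_major + r_tube * np.cos(w)) * np.sin(t_dense),
        r_tube * np.sin(w),
    ])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = spacing * np.arange(n_points)
    if targets[-1] > arc[-1]:
        raise ValueError("toroidal trace too short for requested residue count")
    out = np.empty((n_points, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, arc, pts[:, k])
    return out


def make_toy_structure(
    n_residues: int = DEFAULT_N_RESIDUES,
    n_copies: int = 2,
    seed: int = 0,
    b_factor: float = 15.0,
) -> tuple[AtomModel, list[NCSOperator]]:
    """Build the toy oligomer and the exact NCS operators relating its copies.

    One copy is a toroidal-helix C-alpha trace (3.8 A spacing) with a
    side-chain pseudo-atom 2 A outward of each C-alpha; a second copy, if
    requested, is generated by a proper two-fold rotation about a seeded
    axis, positioned so the copies do not clash.  Operators are returned for
    both mask centers (the two-fold is an involution, so the same rotation
    and translation serve both directions).  Coordinates are centered on the
    origin; deterministic per seed.
    """
    if n_copies not in (1, 2):
        raise ValueError("n_copies must be 1 or 2")
    rng = _rng(seed, 0)
    R_major = 10.0 * (1.0 + 0.05 * rng.uniform(-1, 1))
    r_tube = 4.2 * (1.0 + 0.05 * rng.uniform(-1, 1))
    ca = _toroidal_trace(n_residues, R_major, r_tube)
    ca += rng.normal(scale=0.10, size=ca.shape)  # break exact regularity

    # side-chain pseudo-atoms: 2.0 A outward of the tube axis (centroid-like)
    t_proxy = np.arctan2(ca[:, 1], ca[:, 0])
    tube_center = np.column_stack([
        R_major * np.cos(t_proxy), R_major * np.sin(t_proxy), np.zeros(len(ca))
    ])
    outward = ca - tube_center
    outward /= np.linalg.norm(outward, axis=1, keepdims=True)
    sc = ca + 2.0 * outward

    # random overall orientation
    Rrand = _axis_angle_matrix(rng.normal(size=3), rng.uniform(0, 360))
    ca = ca @ Rrand.T
    sc = sc @ Rrand.T

    def assemble(ca_xyz, sc_xyz, chains):
        n = len(ca_xyz)
        xyz = np.empty((2 * n, 3))
        xyz[0::2] = ca_xyz
        xyz[1::2] = sc_xyz
        roles = [MAIN_CHAIN, SIDE_CHAIN] * n
        resnum = np.repeat(np.arange(1, n + 1), 2)
        return AtomModel(
            element=["C", "C"] * n,
            xyz=xyz,
            B=np.full(2 * n, b_factor),
            occ=np.ones(2 * n),
            chain=[chains] * (2 * n),
            resnum=resnum,
            role=roles,
        )

    copy1 = assemble(ca, sc, "A")
    centroid = copy1.xyz.mean(axis=0)
    extent = float(np.max(np.linalg.norm(copy1.xyz - centroid, axis=1)))
    radius = extent + 3.0

    if n_copies == 1:
        model = copy1.select(np.arange(len(copy1)))
        model.xyz = model.xyz - centroid
        op = NCSOperator(np.eye(3), np.zeros(3), center=np.zeros(3), radius=radius)
        return model, [op]

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    # offset direction perpendicular to the two-fold axis
    perp = np.cross(axis, rng.normal(size=3))
    perp /= np.linalg.norm(perp)
    R2 = _axis_angle_matrix(axis, 180.0)

    gap = extent + 1.0
    from scipy.spatial import cKDTree

    while True:
        axis_point = centroid + perp * gap
        t_op = axis_point - R2 @ axis_point
        xyz2 = copy1.xyz @ R2.T + t_op
        dmin = cKDTree(copy1.xyz).query(xyz2)[0].min()
        if dmin >= 2.0:
            break
        gap += 1.0

    copy2 = assemble(xyz2[0::2], xyz2[1::2], "B")
    xyz_all = np.vstack([copy1.xyz, copy2.xyz])
    shift = xyz_all.mean(axis=0)

    model = AtomModel(
        element=copy1.element + copy2.element,
        xyz=xyz_all - shift,
        B=np.concatenate([copy1.B, copy2.B]),
        occ=np.concatenate([copy1.occ, copy2.occ]),
        chain=copy1.chain + copy2.chain,
        resnum=np.concatenate([copy1.resnum, copy2.resnum]),
        role=copy1.role + copy2.role,
    )
    # two-fold after the recentering shift: x -> R2 x + t' with t' adjusted
    t_adj = t_op + R2 @ shift - shift
    c1 = model.xyz[: len(copy1)].mean(axis=0)
    c2 = model.xyz[len(copy1):].mean(axis=0)
    ops = [
        NCSOperator(R2, t_adj, center=c1, radius=radius),
        NCSOperator(R2, t_adj, center=c2, radius=radius),
    ]
    return model, ops


def simulate_observed(
    truth: AtomModel,
    cell: UnitCell,
    sym: SymmetryOps | None = None,
    d_min: float = XRAY_RESOLUTION,
    amp_noise_frac: float = DEFAULT_AMP_NOISE,
    seed: int = 0,
) -> tuple[ReflectionSet, ReflectionSet]:
    """Observed amplitudes (multiplicative Gaussian noise) and ground-truth
    phases, both from direct-summation structure factors of the truth model."""
    truth_sf = structure_factors_from_model(truth, cell, sym, d_min=d_min)
    rng = _rng(seed, 1)
    noise = rng.normal(scale=amp_noise_frac, size=len(truth_sf)) if amp_noise_frac > 0 else 0.0
    F_obs = np.maximum(truth_sf.F * (1.0 + noise), 0.0)
    obs = ReflectionSet(
        cell=cell,
        hkl=truth_sf.hkl.copy(),
        F=F_obs,
        sigF=amp_noise_frac * truth_sf.F,
    )
    return obs, truth_sf


def simulate_em_map(
    truth: AtomModel,
    cell: UnitCell,
    sym: SymmetryOps | None = None,
    resolution: float = EM_RESOLUTION,
    phase_noise_deg: float = DEFAULT_PHASE_NOISE_DEG,
    B_blur: float = 0.0,
    mag_error: float = 1.0,
    box: bool = False,
    padding_factor: float = 2.0,
    seed: int = 0,
    grid: tuple[int, int, int] | None = None,
) -> tuple[MapGrid, ReflectionSet]:
    """EM-like degraded map of the truth model, plus the phase set it implies.

    Truth structure factors are truncated at the EM resolution, phases are
    perturbed by wrapped-Gaussian noise, and an optional B-factor blur is
    applied.  The returned reflection set carries the noisy phases with a
    constant figure of merit exp(-sigma^2/2) (the expected cosine of the
    injected error).  ``box=True`` additionally re-boxes the density into a
    padded cubic P1 cell (the MR search-model form); ``mag_error`` rescales
    the boxed density to emulate a microscope magnification error.
    """
    sf = structure_factors_from_model(truth, cell, sym, d_min=resolution)
    rng = _rng(seed, 2)
    sigma_rad = np.radians(phase_noise_deg)
    noisy_phi = (sf.phi + rng.normal(scale=phase_noise_deg, size=len(sf))) % 360.0
    fom = np.full(len(sf), np.exp(-0.5 * sigma_rad**2))
    F = sf.F.copy()
    if B_blur:
        F = F * np.exp(-0.25 * B_blur * sf.s2)
    phased = sf.copy(F=F, phi=noisy_phi, fom=fom)
    grid = grid or grid_for_resolution(cell, resolution)
    em_map = map_from_structure_factors(phased, cell, grid)
    if mag_error != 1.0 and not box:
        from .emprep import correct_magnification

        em_map = correct_magnification(em_map, mag_error)
    if box:
        from .emprep import correct_magnification, place_in_p1_box

        boxed, _ = place_in_p1_box(em_map, padding_factor=padding_factor,
                                   d_min=resolution)
        if mag_error != 1.0:
            boxed = correct_magnification(boxed, mag_error)
        em_map = boxed
    return em_map, phased


@dataclass
class ScenarioBundle:
    """Everything one run of the phase-extension experiment needs."""

    seed: int
    cell: UnitCell
    sym: SymmetryOps
    truth_model: AtomModel
    ncs_ops: list[NCSOperator]
    obs: ReflectionSet
    truth_phases: ReflectionSet
    start_phases: ReflectionSet
    em_map: MapGrid
    reference_model: AtomModel
    dm_config: DMConfig
    n_cycles: int = 4
    solvent_fraction_measured: float = 0.5


def measured_solvent_fraction(
    model: AtomModel, cell: UnitCell, atom_radius: float = 4.0,
    grid_step: float = 1.5,
) -> float:
    """Fraction of the cell farther than ``atom_radius`` from any atom.

    The default radius is deliberately generous (4 A, about one smoothing
    length beyond the atomic envelope): the Wang mask that consumes this
    number blurs the molecular boundary, and flattening must err toward
    keeping protein — a mask that bites into the molecule destroys true
    high-resolution signal on every cycle.
    """
    from .densmod import _atom_region_mask

    grid = tuple(max(8, int(np.ceil(L / grid_step))) for L in (cell.a, cell.b, cell.c))
    protein = _atom_region_mask(model, cell, grid, atom_radius)
    return float(1.0 - protein.mean())


def standard_scenario(
    seed: int = 0,
    n_residues: int = DEFAULT_N_RESIDUES,
    cell: UnitCell | None = None,
    d_min: float = XRAY_RESOLUTION,
    em_resolution: float = EM_RESOLUTION,
    amp_noise_frac: float = DEFAULT_AMP_NOISE,
    phase_noise_deg: float = DEFAULT_PHASE_NOISE_DEG,
    n_extension_steps: int = 4,
    n_cycles: int = 4,
) -> ScenarioBundle:
    """One-call fixture mirroring the emulated experiment.

    Deterministic per seed: a two-copy toy structure centered in a P1 cell,
    2.3 A observed amplitudes with 5% noise, a 4.87 A EM-like starting phase
    set with 45 degree phase noise, exact NCS operators, and a DM config
    whose solvent fraction is measured from the ground-truth density and
    whose extension schedule has ``n_extension_steps`` equal shells in 1/d^3.
    """
    cell = cell or UnitCell(*DEFAULT_CELL)
    sym = SymmetryOps.p1()
    model, ops = make_toy_structure(n_residues, n_copies=2, seed=seed)
    center = cell.orthogonalize(np.array([0.5, 0.5, 0.5]))
    model = model.transformed(np.eye(3), center)
    ops = [
        NCSOperator(op.rotation,
                    op.translation + center - op.rotation @ center,
                    center=op.center + center,
                    radius=op.radius)
        for op in ops
    ]

    obs, truth_phases = simulate_observed(
        model, cell, sym, d_min=d_min, amp_noise_frac=amp_noise_frac, seed=seed
    )
    em_map, start_phases = simulate_em_map(
        model, cell, sym, resolution=em_resolution,
        phase_noise_deg=phase_noise_deg, seed=seed,
        grid=grid_for_resolution(cell, d_min),
    )

    solv = measured_solvent_fraction(model, cell)
    dm = DMConfig(
        solvent_fraction=solv,
        extension_schedule=default_extension_schedule(em_resolution, d_min,
                                                      n_extension_steps),
    )
    # generic single-copy model (different fold) for the reference histogram
    ref_model, _ = make_toy_structure(2 * n_residues, n_copies=1,
                                      seed=(seed + 104729) % (2**31 - 1))
    ref_model = ref_model.transformed(np.eye(3), center)

    return ScenarioBundle(
        seed=seed,
        cell=cell,
        sym=sym,
        truth_model=model,
        ncs_ops=ops,
        obs=obs,
        truth_phases=truth_phases,
        start_phases=start_phases,
        em_map=em_map,
        reference_model=ref_model,
        dm_config=dm,
        n_cycles=n_cycles,
        solvent_fraction_measured=solv,
    )
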