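"""File I/O: columnar reflection text, CCP4/MRC maps and PDB models.

Map and model I/O are delegated to gemmi; reflection files are the plain
whitespace-columnar text with header ``h k l F sigF phi fom`` (missing
columns allowed).  MTZ read/write is available behind the same surface
when wanted (gemmi provides it natively).
"""

from __future__ import annotations

import numpy as np

from .core import AtomModel, MapGrid, ReflectionSet, UnitCell

__all__ = [
    "read_hkl",
    "write_hkl",
    "read_map",
    "write_map",
    "read_pdb",
    "write_pdb",
    "read_mtz",
    "write_mtz",
]

_HKL_COLUMNS = ("h", "k", "l", "F", "sigF", "phi", "fom")


def write_hkl(path: str, refl: ReflectionSet) -> None:
    cols: list[str] = ["h", "k", "l", "F"]
    data: list[np.ndarray] = [refl.hkl[:, 0], refl.hkl[:, 1], refl.hkl[:, 2], refl.F]
    for name in ("sigF", "phi", "fom"):
        v = getattr(refl, name)
        if v is not None:
            cols.append(name)
            data.append(v)
    with open(path, "w") as fh:
        fh.write("# cell "
                 f"{refl.cell.a:.6g} {refl.cell.b:.6g} {refl.cell.c:.6g} "
                 f"{refl.cell.alpha:.6g} {refl.cell.beta:.6g} {refl.cell.gamma:.6g}\n")
        fh.write(" ".join(cols) + "\n")
        arr = np.column_stack(data)
        for row in arr:
            fields = [f"{int(x):d}" if c in "hkl" else f"{x:.6f}" for c, x in zip(cols, row)]
            fh.write(" ".join(fields) + "\n")


def read_hkl(path: str, cell: UnitCell | None = None) -> ReflectionSet:
    """Read columnar reflection text.  The cell comes from a ``# cell`` comment
    line if present, else must be supplied."""
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "cell" and len(parts) == 7:
                    cell = UnitCell(*map(float, parts[1:]))
                continue
            toks = line.replace(",", " ").split()
            if header is None and any(t.lower() in ("h", "f") for t in toks):
                header = [t for t in toks]
                continue
            rows.append([float(t) for t in toks])
    if cell is None:
        raise ValueError(f"{path}: no unit cell in file and none supplied")
    if header is None:
        header = list(_HKL_COLUMNS[: len(rows[0])])
    lower = [h.lower() for h in header]
    arr = np.asarray(rows, float)

    def col(name: str) -> np.ndarray | None:
        return arr[:, lower.index(name.lower())] if name.lower() in lower else None

    hkl = np.column_stack([col("h"), col("k"), col("l")]).astype(int)
    return ReflectionSet(
        cell=cell,
        hkl=hkl,
        F=col("F"),
        sigF=col("sigF"),
        phi=col("phi"),
        fom=col("fom"),
    )


# --------------------------------------------------------------------------
# maps (CCP4/MRC 2014, mode 2)


def write_map(path: str, map_: MapGrid) -> None:
    import gemmi

    grid = gemmi.FloatGrid(*map_.shape)
    c = map_.cell
    grid.set_unit_cell(gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma))
    grid.spacegroup = gemmi.SpaceGroup("P1")
    np.asarray(grid, dtype=np.float32)[...] = map_.rho.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(2, True)  # mode 2 = 32-bit float
    ccp4.write_ccp4_map(path)


def read_map(path: str) -> MapGrid:
    import gemmi

    ccp4 = gemmi.read_ccp4_map(path)
    ccp4.setup(float("nan"))
    g = ccp4.grid
    cell = UnitCell(
        g.unit_cell.a, g.unit_cell.b, g.unit_cell.c,
        g.unit_cell.alpha, g.unit_cell.beta, g.unit_cell.gamma,
    )
    return MapGrid(cell, np.array(g, dtype=float))


# --------------------------------------------------------------------------
# models (PDB, ATOM/HETATM only)

_ROLE_TO_NAME = {"main": "CA", "side": "CB"}
_NAME_TO_ROLE = {"CA": "main", "CB": "side"}


def write_pdb(path: str, model: AtomModel, cell: UnitCell | None = None) -> None:
    lines = []
    if cell is not None:
        lines.append(
            f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
            f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} P 1           1"
        )
    for i in range(len(model)):
        name = _ROLE_TO_NAME.get(model.role[i], "CA")
        x, y, z = model.xyz[i]
        el = model.element[i].strip().upper()
        el = el if el in ("C", "N", "O", "S") else "C"
        lines.append(
            f"ATOM  {i + 1:5d} {name:>4s} ALA {model.chain[i][:1]:1s}"
            f"{int(model.resnum[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{model.occ[i]:6.2f}{model.B[i]:6.2f}"
            f"          {el:>2s}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\nEND\n")


def read_pdb(path: str) -> tuple[AtomModel, UnitCell | None]:
    import gemmi

    st = gemmi.read_structure(path)
    cell = None
    if st.cell and st.cell.a > 1.0:
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
    element, xyz, B, occ, chain, resnum, role = [], [], [], [], [], [], []
    for model in st:
        for ch in model:
            for res in ch:
                for atom in res:
                    element.append(atom.element.name or "C")
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    B.append(atom.b_iso if atom.b_iso > 0 else 20.0)
                    occ.append(min(max(atom.occ, 1e-6), 1.0))
                    chain.append(ch.name)
                    resnum.append(res.seqid.num)
                    role.append(_NAME_TO_ROLE.get(atom.name.strip(), "main"))
        break  # first model only
    return (
        AtomModel(element=element, xyz=np.array(xyz), B=np.array(B),
                  occ=np.array(occ), chain=chain, resnum=np.array(resnum), role=role),
        cell,
    )


# --------------------------------------------------------------------------
# MTZ (feature-flagged convenience; gemmi does the work)


def write_mtz(path: str, refl: ReflectionSet) -> None:
    import gemmi

    mtz = gemmi.Mtz(with_base=True)
    c = refl.cell
    mtz.set_cell_for_all(gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma))
    mtz.spacegroup = gemmi.SpaceGroup("P1")
    mtz.add_dataset("phaseloop")
    mtz.add_column("F", "F")
    cols = [refl.hkl[:, 0], refl.hkl[:, 1], refl.hkl[:, 2], refl.F]
    if refl.sigF is not None:
        mtz.add_column("SIGF", "Q")
        cols.append(refl.sigF)
    if refl.phi is not None:
        mtz.add_column("PHI", "P")
        cols.append(refl.phi)
    if refl.fom is not None:
        mtz.add_column("FOM", "W")
        cols.append(refl.fom)
    mtz.set_data(np.column_stack(cols).astype(np.float32))
    mtz.write_to_file(path)


def read_mtz(path: str) -> ReflectionSet:
    import gemmi

    mtz = gemmi.read_mtz_file(path)
    arr = np.array(mtz, copy=True)
    labels = [c.label for c in mtz.columns]

    def col(name: str) -> np.ndarray | None:
        return arr[:, labels.index(name)] if name in labels else None

    cell = UnitCell(mtz.cell.a, mtz.cell.b, mtz.cell.c,
                    mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma)
    hkl = np.column_stack([col("H"), col("K"), col("L")]).astype(int)
    return ReflectionSet(cell=cell, hkl=hkl, F=col("F"), sigF=col("SIGF"),
                         phi=col("PHI"), fom=col("FOM"))
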