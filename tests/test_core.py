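"""Unit-cell geometry and map<->structure-factor transforms, validated
against closed forms, a brute-force DFT, and gemmi's cell arithmetic."""

import numpy as np
import pytest

import phaseloop as pl
from phaseloop.core import FORM_FACTORS, hemisphere_mask


class TestResolution:
    def test_axial_reflection_cubic(self, cubic_cell):
        assert pl.resolution_of((1, 0, 0), cubic_cell) == pytest.approx(10.0)

    def test_body_diagonal_cubic(self, cubic_cell):
        assert pl.resolution_of((1, 1, 1), cubic_cell) == pytest.approx(10.0 / np.sqrt(3))

    def test_triclinic_against_gemmi(self):
        gemmi = pytest.importorskip("gemmi")
        cell = pl.UnitCell(10, 12, 15, 80, 95, 100)
        ref = gemmi.UnitCell(10, 12, 15, 80, 95, 100)
        for hkl in [(2, 1, 3), (1, 0, 0), (-3, 2, -1), (0, 5, 2)]:
            assert pl.resolution_of(hkl, cell) == pytest.approx(
                ref.calculate_d(hkl), abs=1e-9
            )

    def test_friedel_invariance(self, rng):
        cell = pl.UnitCell(10, 12, 15, 80, 95, 100)
        hkl = rng.integers(-5, 6, size=(50, 3))
        hkl = hkl[hkl.any(axis=1)]
        np.testing.assert_allclose(
            pl.resolution_of(hkl, cell), pl.resolution_of(-hkl, cell), rtol=1e-12
        )

    def test_f000_rejected(self, cubic_cell):
        with pytest.raises(ValueError, match="F000"):
            pl.resolution_of((0, 0, 0), cubic_cell)


class TestMapToStructureFactors:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fft_agrees_with_direct_dft(self, seed, cubic_cell):
        """FFT path vs explicit O(N*M) direct DFT sum on an 8^3 map."""
        rng = np.random.default_rng(seed)
        m = pl.MapGrid(cubic_cell, rng.normal(size=(8, 8, 8)))
        sf = pl.structure_factors_from_map(m, 4.0)
        frac = m.voxel_frac_coords()
        rho = m.rho.ravel()
        F = np.array(
            [cubic_cell.volume * np.mean(rho * np.exp(2j * np.pi * (frac @ h)))
             for h in sf.hkl]
        )
        rel = np.sqrt(np.mean(np.abs(F - sf.complex_F()) ** 2)
                      / np.mean(np.abs(F) ** 2))
        assert rel < 1e-10

    def test_constant_map_has_zero_coefficients(self, cubic_cell):
        m = pl.MapGrid(cubic_cell, np.full((8, 8, 8), 3.7))
        sf = pl.structure_factors_from_map(m, 4.0)
        assert np.all(sf.F < 1e-10)

    def test_single_cosine_mode(self, cubic_cell):
        x = np.arange(12) / 12.0
        rho = np.broadcast_to(np.cos(2 * np.pi * x)[:, None, None], (12, 12, 12))
        sf = pl.structure_factors_from_map(pl.MapGrid(cubic_cell, rho.copy()), 4.0)
        big = sf.F > 1e-8 * sf.F.max()
        assert np.array_equal(sf.hkl[big], [[1, 0, 0]])
        assert sf.phi[big][0] == pytest.approx(0.0, abs=1e-6)
        # F(h) = V * <rho cos term> = V/2 for a unit cosine
        assert sf.F[big][0] == pytest.approx(cubic_cell.volume / 2.0, rel=1e-10)

    def test_grid_too_coarse_raises(self, cubic_cell):
        m = pl.MapGrid(cubic_cell, np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match="divisions"):
            pl.structure_factors_from_map(m, 2.0)

    def test_hemisphere_and_no_f000(self, cubic_cell, rng):
        m = pl.MapGrid(cubic_cell, rng.normal(size=(10, 10, 10)))
        sf = pl.structure_factors_from_map(m, 4.0)
        assert hemisphere_mask(sf.hkl).all()
        assert not np.any(~sf.hkl.any(axis=1))


class TestMapSynthesis:
    def test_round_trip_band_limited(self, cubic_cell, rng):
        m0 = pl.MapGrid(cubic_cell, rng.normal(size=(12, 12, 12)))
        sf = pl.structure_factors_from_map(m0, 3.0)
        m1 = pl.map_from_structure_factors(sf, cubic_cell, (12, 12, 12))
        sf1 = pl.structure_factors_from_map(m1, 3.0)
        assert np.allclose(sf1.complex_F(), sf.complex_F(),
                           atol=1e-8 * sf.F.max())
        # synthesizing again reproduces the map exactly (FFT inverse pair)
        m2 = pl.map_from_structure_factors(sf1, cubic_cell, (12, 12, 12))
        assert np.abs(m2.rho - m1.rho).max() < 1e-8 * np.abs(m1.rho).max()

    def test_zero_fom_gives_flat_map(self, cubic_cell, rng):
        m0 = pl.MapGrid(cubic_cell, rng.normal(size=(8, 8, 8)))
        sf = pl.structure_factors_from_map(m0, 4.0)
        sf.fom = np.zeros(len(sf))
        flat = pl.map_from_structure_factors(sf, cubic_cell, (8, 8, 8),
                                             use_fom_weights=True)
        assert np.abs(flat.rho).max() == 0.0

    def test_single_reflection_sine_wave(self, cubic_cell):
        refl = pl.ReflectionSet(cell=cubic_cell, hkl=[[1, 0, 0]], F=[1.0],
                                phi=[90.0])
        m = pl.map_from_structure_factors(refl, cubic_cell, (16, 16, 16))
        # rho(x) = (2/V) cos(2 pi x - pi/2) = (2/V) sin(2 pi x)
        x = np.arange(16) / 16.0
        expect = (2.0 / cubic_cell.volume) * np.sin(2 * np.pi * x)
        np.testing.assert_allclose(m.rho[:, 0, 0], expect, atol=1e-12)

    def test_missing_phases_raise(self, cubic_cell):
        refl = pl.ReflectionSet(cell=cubic_cell, hkl=[[1, 0, 0]], F=[1.0])
        with pytest.raises(ValueError, match="phases"):
            pl.map_from_structure_factors(refl, cubic_cell, (8, 8, 8))

    def test_parseval(self, cubic_cell, rng):
        m0 = pl.MapGrid(cubic_cell, rng.normal(size=(12, 12, 12)))
        sf = pl.structure_factors_from_map(m0, 3.0)
        m = pl.map_from_structure_factors(sf, cubic_cell, (12, 12, 12))
        total = 2.0 * np.sum(sf.F**2)  # both Friedel hemispheres
        rhs = cubic_cell.volume**2 * np.mean(m.rho**2)
        assert total == pytest.approx(rhs, rel=1e-6)


class TestModelStructureFactors:
    def test_origin_atom(self, cubic_cell):
        model = pl.AtomModel(element=["C"], xyz=[[0.0, 0.0, 0.0]], B=[1e-9],
                             occ=[1.0])
        model.B = np.array([1e-9])  # effectively B=0
        sf = pl.structure_factors_from_model(model, cubic_cell, d_min=3.0)
        a, b = FORM_FACTORS["C"]
        np.testing.assert_allclose(sf.F, a * np.exp(-0.25 * b * sf.s2), rtol=1e-6)
        wrapped = np.minimum(sf.phi, 360.0 - sf.phi)
        assert wrapped.max() < 1e-6

    def test_centrosymmetric_pair(self, cubic_cell):
        model = pl.AtomModel(element=["C", "C"],
                             xyz=[[1.3, 2.1, 0.7], [-1.3, -2.1, -0.7]],
                             B=[15.0, 15.0], occ=[1.0, 1.0])
        sf = pl.structure_factors_from_model(model, cubic_cell, d_min=3.0)
        dist = np.minimum(sf.phi % 180.0, 180.0 - sf.phi % 180.0)
        assert dist[sf.F > 1e-6 * sf.F.max()].max() < 1e-5

    def test_against_gaussian_raster(self, cubic_cell, ten_atom_model):
        """Direct summation equals FFT of the sampled Gaussian density."""
        sfm = pl.structure_factors_from_model(ten_atom_model, cubic_cell, d_min=2.5)
        gm = pl.gaussian_density_from_model(ten_atom_model, cubic_cell, (32, 32, 32))
        sfg = pl.structure_factors_from_map(gm, 2.5)
        ia, ib = sfm.match(sfg)
        rel = np.sqrt(np.mean((sfm.F[ia] - sfg.F[ib]) ** 2)
                      / np.mean(sfm.F[ia] ** 2))
        assert rel < 0.02

    def test_unknown_element_falls_back_to_dummy(self, cubic_cell):
        model = pl.AtomModel(element=["Zz"], xyz=[[1.0, 1.0, 1.0]], B=[10.0],
                             occ=[1.0])
        sf = pl.structure_factors_from_model(model, cubic_cell, d_min=4.0)
        assert sf.warn and "dummy" in sf.warn[0]

    def test_empty_model_raises(self, cubic_cell):
        model = pl.AtomModel(element=[], xyz=np.empty((0, 3)), B=np.empty(0),
                             occ=np.empty(0))
        with pytest.raises(ValueError, match="no atoms"):
            pl.structure_factors_from_model(model, cubic_cell)


class TestReflectionSetValidation:
    def test_duplicates_rejected(self, cubic_cell):
        with pytest.raises(ValueError, match="duplicated"):
            pl.ReflectionSet(cell=cubic_cell, hkl=[[1, 0, 0], [1, 0, 0]],
                             F=[1.0, 2.0])

    def test_f000_rejected(self, cubic_cell):
        with pytest.raises(ValueError, match="F000"):
            pl.ReflectionSet(cell=cubic_cell, hkl=[[0, 0, 0]], F=[1.0])

    def test_bad_fom_rejected(self, cubic_cell):
        with pytest.raises(ValueError, match="fom"):
            pl.ReflectionSet(cell=cubic_cell, hkl=[[1, 0, 0]], F=[1.0], fom=[1.5])

    def test_negative_amplitude_rejected(self, cubic_cell):
        with pytest.raises(ValueError, match="non-negative"):
            pl.ReflectionSet(cell=cubic_cell, hkl=[[1, 0, 0]], F=[-1.0])

    def test_d_matches_cell_metric(self, cubic_cell, rng):
        m = pl.MapGrid(cubic_cell, rng.normal(size=(8, 8, 8)))
        sf = pl.structure_factors_from_map(m, 4.0)
        np.testing.assert_allclose(sf.d, cubic_cell.d_spacing(sf.hkl), atol=1e-6)


class TestSymmetryOps:
    def test_identity_first_and_deduplicated(self):
        sym = pl.SymmetryOps([(np.eye(3), [0, 0, 0])])
        assert len(sym) == 1
        R, t = sym[0]
        assert np.allclose(R, np.eye(3)) and np.allclose(t, 0)

    def test_p21_centric_flags(self):
        sym = pl.SymmetryOps.p21_b()
        # h0l reflections are centric in P2_1 (b unique)
        assert sym.is_centric(np.array([[3, 0, 2]]))[0]
        assert not sym.is_centric(np.array([[3, 1, 2]]))[0]


class TestFileIO:
    def test_hkl_round_trip(self, tmp_path, cubic_cell, rng):
        m = pl.MapGrid(cubic_cell, rng.normal(size=(8, 8, 8)))
        sf = pl.structure_factors_from_map(m, 4.0)
        sf.fom = rng.uniform(0, 1, len(sf))
        path = tmp_path / "test.hkl"
        pl.io.write_hkl(str(path), sf)
        back = pl.io.read_hkl(str(path))
        ia, ib = sf.match(back)
        assert len(ia) == len(sf)
        np.testing.assert_allclose(back.F[ib], sf.F[ia], atol=1e-5)
        np.testing.assert_allclose(back.phi[ib], sf.phi[ia], atol=1e-5)
        np.testing.assert_allclose(back.fom[ib], sf.fom[ia], atol=1e-5)

    def test_map_round_trip(self, tmp_path, cubic_cell, rng):
        m = pl.MapGrid(cubic_cell, rng.normal(size=(8, 10, 12)))
        path = tmp_path / "test.mrc"
        pl.io.write_map(str(path), m)
        back = pl.io.read_map(str(path))
        assert back.cell.a == pytest.approx(10.0, abs=1e-4)
        np.testing.assert_allclose(back.rho, m.rho, atol=1e-5)

    def test_pdb_round_trip(self, tmp_path, ten_atom_model, cubic_cell):
        path = tmp_path / "test.pdb"
        pl.io.write_pdb(str(path), ten_atom_model, cubic_cell)
        back, cell = pl.io.read_pdb(str(path))
        assert cell.a == pytest.approx(10.0, abs=1e-3)
        np.testing.assert_allclose(back.xyz, ten_atom_model.xyz, atol=1e-3)
        np.testing.assert_allclose(back.B, ten_atom_model.B, atol=1e-2)

    def test_mtz_round_trip(self, tmp_path, cubic_cell, rng):
        gemmi = pytest.importorskip("gemmi")
        m = pl.MapGrid(cubic_cell, rng.normal(size=(8, 8, 8)))
        sf = pl.structure_factors_from_map(m, 4.0)
        path = tmp_path / "test.mtz"
        pl.io.write_mtz(str(path), sf)
        back = pl.io.read_mtz(str(path))
        ia, ib = sf.match(back)
        assert len(ia) == len(sf)
        np.testing.assert_allclose(back.F[ib], sf.F[ia], rtol=1e-5)
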