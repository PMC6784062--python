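import numpy as np
import pytest

import fibercell as fc
from fibercell.diffraction import (
    DisorderModel,
    ReflectionSet,
    apply_lateral_disorder,
    collapse_multiplets,
    enumerate_reflections,
    fourier_synthesis,
    structure_factors,
)
from tests.conftest import brute_force_structure_factor


class TestEnumerateReflections:
    def test_matches_exhaustive_scan(self, fish_cell):
        hkl = enumerate_reflections(fish_cell, 60.0, range(0, 7))
        got = {tuple(x) for x in hkl}
        expect = set()
        for h in range(-20, 21):
            for k in range(-20, 21):
                for l in range(0, 7):
                    if (h, k, l) == (0, 0, 0):
                        continue
                    if fc.d_spacing(fish_cell, h, k, l) >= 60.0 - 1e-9:
                        expect.add((h, k, l))
        assert got == expect

    def test_layer_line_boundary_at_resolution_cutoff(self, fish_cell):
        # c/7 = 61.4 Å >= 60 so l=7 has a meridional entry; c/8 < 60 and the
        # meridian falls outside the cutoff
        l7 = enumerate_reflections(fish_cell, 60.0, [7])
        assert (0, 0, 7) in {tuple(x) for x in l7}
        with pytest.raises(ValueError, match="smaller d_min"):
            enumerate_reflections(fish_cell, 60.0, [8])

    def test_excluded_layer_line_absent(self, insect_cell):
        hkl = enumerate_reflections(insect_cell, 60.0, [5, 8, 11, 13, 16])
        assert 3 not in set(hkl[:, 2])

    def test_r_max_caps_equatorial_extent(self, fish_cell):
        hkl = enumerate_reflections(fish_cell, 60.0, [0], r_max=0.01)
        refl = ReflectionSet(fish_cell, hkl, np.ones(len(hkl)))
        assert refl.r_perp.max() <= 0.01 + 1e-12


class TestStructureFactor:
    def test_origin_scatterer_gives_constant_f(self, fish_cell):
        model = fc.FilamentModel(np.zeros((1, 3)), np.array([3.5]),
                                 axial_repeat=429.6)
        placed = fc.place_filament(fish_cell, model, 0.0)
        for h, k, l in [(0, 0, 0), (3, -2, 5), (7, 0, 1)]:
            assert fc.structure_factor(placed, h, k, l) == pytest.approx(3.5)

    def test_half_period_pair_cancels_odd_meridionals(self, fish_cell):
        pos = np.array([[30.0, 10.0, 0.0], [30.0, 10.0, 429.6 / 2]])
        model = fc.FilamentModel(pos, np.ones(2), axial_repeat=429.6)
        placed = fc.place_filament(fish_cell, model, 0.0)
        for l in (1, 3, 5):
            assert abs(fc.structure_factor(placed, 0, 0, l)) < 1e-10
        assert fc.structure_factor(placed, 0, 0, 2) == pytest.approx(2.0)

    def test_matches_bruteforce_on_random_model(self, fish_cell, random_model):
        placed = fc.place_filament(fish_cell, random_model, 13.0)
        hkl = enumerate_reflections(fish_cell, 80.0, range(0, 5))
        refl = structure_factors(placed, hkl)
        rng = np.random.default_rng(0)
        for i in rng.choice(len(refl), size=40, replace=False):
            h, k, l = refl.hkl[i]
            oracle = brute_force_structure_factor(placed, h, k, l)
            assert abs(refl.F[i] - oracle) <= 1e-9 * max(1.0, abs(oracle))

    def test_friedel_symmetry(self, fish_cell, random_model):
        placed = fc.place_filament(fish_cell, random_model, 5.0)
        hkl = np.array([[2, 1, 3], [-2, -1, -3], [4, 0, 1], [-4, 0, -1]])
        refl = structure_factors(placed, hkl)
        assert refl.I[0] == pytest.approx(refl.I[1], rel=1e-9)
        assert refl.I[2] == pytest.approx(refl.I[3], rel=1e-9)

    def test_linearity_over_scatterer_union(self, fish_cell):
        rng = np.random.default_rng(11)
        posA = rng.uniform(-100, 100, (20, 3))
        posB = rng.uniform(-100, 100, (15, 3))
        wA, wB = rng.uniform(1, 5, 20), rng.uniform(1, 5, 15)
        mkp = lambda p, w: fc.place_filament(
            fish_cell, fc.FilamentModel(p, w, axial_repeat=429.6), 0.0)
        hkl = np.array([[1, 0, 2], [3, 2, 1], [0, 0, 3]])
        FA = structure_factors(mkp(posA, wA), hkl).F
        FB = structure_factors(mkp(posB, wB), hkl).F
        FU = structure_factors(
            mkp(np.vstack([posA, posB]), np.concatenate([wA, wB])), hkl).F
        np.testing.assert_allclose(FU, FA + FB, rtol=1e-10)


class TestMultiplets:
    def test_53_and_70_collapse_together(self, fish_cell, small_toy):
        placed = fc.place_filament(fish_cell, small_toy, 10.0)
        hkl = np.array([[5, 3, 2], [7, 0, 2]])
        table = collapse_multiplets(structure_factors(placed, hkl))
        assert len(table) == 1
        assert table.s[0] == 49
        assert set(table.members[0]) == {(5, 3), (7, 0)}

    def test_single_reflection_intensity_unchanged(self, fish_cell, small_toy):
        placed = fc.place_filament(fish_cell, small_toy, 0.0)
        refl = structure_factors(placed, np.array([[1, 0, 3]]))
        table = collapse_multiplets(refl)
        assert len(table) == 1
        assert table.intensity[0] == pytest.approx(refl.I[0])

    def test_total_intensity_conserved(self, fish_cell, small_toy):
        placed = fc.place_filament(fish_cell, small_toy, 23.0)
        hkl = enumerate_reflections(fish_cell, 60.0, range(0, 7))
        refl = structure_factors(placed, hkl)
        table = collapse_multiplets(refl)
        assert table.total_intensity == pytest.approx(refl.I.sum(), rel=1e-12)
        assert sum(len(m) for m in table.members) == len(refl)

    def test_integer_grouping_matches_float_radius_grouping(self, fish_cell):
        # oracle: group by rounded float radius with 1e-9 tolerance
        rng = np.random.default_rng(5)
        hkl = np.unique(rng.integers(-8, 9, size=(120, 3)), axis=0)
        hkl = hkl[~np.all(hkl == 0, axis=1)]
        hkl[:, 2] = np.abs(hkl[:, 2])
        refl = ReflectionSet(fish_cell, hkl,
                             rng.normal(size=len(hkl))
                             + 1j * rng.normal(size=len(hkl)))
        table = collapse_multiplets(refl)
        groups = {}
        for (h, k, l), I in zip(refl.hkl, refl.I):
            r = fc.reciprocal_radius(fish_cell, h, k)
            key = (l, round(r / 1e-9))
            groups[key] = groups.get(key, 0.0) + I
        assert len(groups) == len(table)
        for (l, s), I in zip(zip(table.l, table.s), table.intensity):
            r = np.sqrt(4 * s / (3 * fish_cell.a**2))
            assert groups[(l, round(r / 1e-9))] == pytest.approx(I, rel=1e-9)

    def test_rotating_by_symmetry_leaves_multiplets_unchanged(
            self, fish_cell, vertebrate_toy):
        hkl = enumerate_reflections(fish_cell, 60.0, range(1, 7))
        tables = []
        for ang in (14.0, 14.0 + 120.0):
            placed = fc.place_filament(fish_cell, vertebrate_toy, ang)
            tables.append(collapse_multiplets(structure_factors(placed, hkl)))
        np.testing.assert_allclose(tables[0].intensity, tables[1].intensity,
                                   rtol=1e-9)


class TestLateralDisorder:
    def _table(self, fish_cell, small_toy):
        placed = fc.place_filament(fish_cell, small_toy, 0.0)
        hkl = enumerate_reflections(fish_cell, 60.0, range(0, 7))
        return collapse_multiplets(structure_factors(placed, hkl))

    def test_zero_sigma_is_identity(self, fish_cell, small_toy):
        table = self._table(fish_cell, small_toy)
        out = apply_lateral_disorder(table, DisorderModel(0.0))
        np.testing.assert_array_equal(out.intensity, table.intensity)

    def test_meridional_rows_unchanged(self, fish_cell, small_toy):
        table = self._table(fish_cell, small_toy)
        out = apply_lateral_disorder(table, DisorderModel(50.0))
        merid = table.s == 0
        assert merid.any()
        np.testing.assert_allclose(out.intensity[merid],
                                   table.intensity[merid], rtol=1e-12)
        assert np.all(out.intensity[~merid] < table.intensity[~merid])

    def test_attenuation_formula(self):
        sigma, r = 20.0, 0.01
        expect = np.exp(-2.0 * np.pi**2 * sigma**2 * r**2)
        assert DisorderModel(sigma).attenuation(np.array([r]))[0] == \
            pytest.approx(expect, rel=1e-12)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            DisorderModel(-1.0)


class TestFourierSynthesis:
    def test_dc_term_gives_uniform_grid(self, fish_cell):
        refl = ReflectionSet(fish_cell, np.array([[0, 0, 0]]),
                             np.array([100.0 + 0j]))
        grid = fourier_synthesis(refl, (8, 8, 8))
        np.testing.assert_allclose(grid.values, 100.0 / fish_cell.volume,
                                   rtol=1e-12)

    def test_blob_peak_at_blob_position(self, fish_cell):
        rng = np.random.default_rng(2)
        centre_frac = np.array([0.25, 0.5, 0.125])
        centre = fish_cell.orthogonalize(centre_frac)
        pos = centre + rng.normal(0, 8.0, size=(200, 3))
        model = fc.FilamentModel(pos, np.ones(200), axial_repeat=429.6)
        placed = fc.PlacedCell(fish_cell, fish_cell.fractionalize(pos) % 1.0,
                               model.weights)
        hkl = np.vstack([[0, 0, 0],
                         enumerate_reflections(fish_cell, 50.0, range(0, 9))])
        grid = fourier_synthesis(structure_factors(placed, hkl), (16, 16, 16))
        peak = np.unravel_index(np.argmax(grid.values), grid.values.shape)
        np.testing.assert_allclose(np.array(peak) / 16.0, centre_frac,
                                   atol=1.0 / 16)

    def test_round_trip_correlation_against_fft_oracle(self, fish_cell,
                                                       small_toy):
        placed = fc.place_filament(fish_cell, small_toy, 0.0)
        hkl = np.vstack([[0, 0, 0],
                         enumerate_reflections(fish_cell, 60.0, range(0, 7))])
        refl = structure_factors(placed, hkl)
        n = 20
        grid = fourier_synthesis(refl, (n, n, n))
        # independent oracle: brute-force F placed into an FFT array
        arr = np.zeros((n, n, n), complex)
        seen = {}
        for (h, k, l) in map(tuple, hkl):
            F = brute_force_structure_factor(placed, h, k, l)
            seen[(h, k, l)] = F
            if (-h, -k, -l) not in seen and (h, k, l) != (0, 0, 0):
                seen[(-h, -k, -l)] = np.conj(F)
        for (h, k, l), F in seen.items():
            arr[h % n, k % n, l % n] += F
        ref = np.fft.fftn(arr).real / fish_cell.volume
        corr = np.corrcoef(grid.values.ravel(), ref.ravel())[0, 1]
        assert corr >= 0.99

    def test_imaginary_residual_detected(self, fish_cell):
        # a lone non-Friedel-paired reflection cannot give a real density,
        # but completion is automatic; forcing both mates with
        # non-conjugate F must raise
        refl = ReflectionSet(fish_cell, np.array([[1, 0, 1], [-1, 0, -1]]),
                             np.array([1 + 1j, 1 + 1j]))
        with pytest.raises(ValueError, match="imaginary"):
            fourier_synthesis(refl, (8, 8, 8))
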