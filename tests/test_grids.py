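"""FragMap grid data model, Boltzmann transform, nearest-voxel lookup, DX I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fragdock import (
    KB_KCAL,
    FragMapGrid,
    FragMapSet,
    boltzmann_transform,
    gfe_at,
    read_gfe_map,
    write_gfe_map,
)
from fragdock.grids import GridParseError, gfe_at_many


class TestBoltzmannTransform:
    @pytest.mark.parametrize(
        "prob, temperature, cap, expected",
        [
            (1.0, 300.0, 3.0, 0.0),  # bulk occupancy is the zero of the scale
            (0.0, 300.0, 3.0, 3.0),  # unvisited voxel takes the cap
            (2.0, 300.0, 3.0, -KB_KCAL * 300.0 * math.log(2.0)),  # ~-0.4132
            (1e-6, 300.0, 3.0, 3.0),  # strongly depleted voxel hits the cap
        ],
    )
    def test_pointwise_values(self, prob, temperature, cap, expected):
        out = boltzmann_transform(np.array([prob]), temperature, cap)
        assert out[0] == pytest.approx(expected, abs=1e-9)

    def test_matches_analytic_form_on_array(self, rng):
        p = rng.uniform(0.0, 3.0, size=(4, 4, 4))
        out = boltzmann_transform(p, 310.0, 3.0)
        with np.errstate(divide="ignore"):
            ref = np.minimum(np.where(p > 0, -KB_KCAL * 310.0 * np.log(p), 3.0), 3.0)
        np.testing.assert_allclose(out, ref, atol=1e-9)

    def test_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError):
            boltzmann_transform(np.array([-0.1]))
        with pytest.raises(ValueError):
            boltzmann_transform(np.array([np.nan]))
        with pytest.raises(ValueError):
            boltzmann_transform(np.array([1.0]), temperature=0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3), st.floats(min_value=1e-3, max_value=1e3))
    def test_monotone_decreasing_in_probability(self, p1, p2):
        lo, hi = sorted([p1, p2])
        g = boltzmann_transform(np.array([lo, hi]), 300.0, gfe_cap=1e6)
        assert g[0] >= g[1]


class TestGridModel:
    def test_values_capped_on_construction(self):
        g = FragMapGrid("GENN", np.zeros(3), np.ones(3), np.full((2, 2, 2), 10.0), gfe_cap=3.0)
        assert np.all(g.values == 3.0)

    def test_invalid_spacing_and_nonfinite_values(self):
        with pytest.raises(ValueError):
            FragMapGrid("GENN", np.zeros(3), np.array([1.0, 0.0, 1.0]), np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            FragMapGrid("GENN", np.zeros(3), np.ones(3), np.full((2, 2, 2), np.inf))

    def test_set_requires_congruent_grids(self, random_grid):
        other = FragMapGrid("GEND", random_grid.origin + 1.0, random_grid.spacing,
                            random_grid.values.copy())
        with pytest.raises(ValueError, match="congruent"):
            FragMapSet({"GENN": random_grid, "GEND": other})
        with pytest.raises(ValueError):
            FragMapSet({})


class TestGfeAt:
    def test_voxel_center_and_outside(self, random_grid):
        assert gfe_at(random_grid, random_grid.voxel_center((1, 2, 3))) == random_grid.values[1, 2, 3]
        assert gfe_at(random_grid, random_grid.origin - 10.0) == random_grid.gfe_cap

    def test_point_just_inside_voxel_boundary(self, random_grid):
        center = random_grid.voxel_center((2, 2, 2))
        shifted = center + 0.49 * random_grid.spacing
        assert gfe_at(random_grid, shifted) == random_grid.values[2, 2, 2]

    def test_nonfinite_coordinates_rejected(self, random_grid):
        with pytest.raises(ValueError):
            gfe_at(random_grid, [np.nan, 0, 0])

    def test_matches_bruteforce_nearest_center(self, random_grid, rng):
        """Nearest-voxel lookup == argmin over voxel-center distances."""
        lo = random_grid.origin - 0.4 * random_grid.spacing
        hi = random_grid.voxel_center((4, 4, 4)) + 0.4 * random_grid.spacing
        pts = rng.uniform(lo, hi, size=(1000, 3))
        centers = np.array(
            [random_grid.voxel_center((i, j, k)) for i in range(5) for j in range(5) for k in range(5)]
        )
        flat = random_grid.values.reshape(-1)
        for p in pts:
            nearest = int(np.argmin(((centers - p) ** 2).sum(axis=1)))
            assert gfe_at(random_grid, p) == flat[nearest]

    def test_vectorized_lookup_agrees_with_scalar(self, random_grid, rng):
        pts = rng.uniform(-5, 8, size=(200, 3))
        many = gfe_at_many(random_grid, pts)
        each = np.array([gfe_at(random_grid, p) for p in pts])
        np.testing.assert_array_equal(many, each)


HANDCRAFTED_DX = """# test map
object 1 class gridpositions counts 2 2 2
origin 0.000000 0.000000 0.000000
delta 1.000000 0.000000 0.000000
delta 0.000000 1.000000 0.000000
delta 0.000000 0.000000 1.000000
object 2 class gridconnections counts 2 2 2
object 3 class array type double rank 0 items 8 data follows
0.0 1.0 2.0
3.0 4.0 5.0
6.0 7.0
attribute "dep" string "positions"
"""


class TestOpenDxIO:
    def test_handcrafted_file_parses_z_fastest(self, tmp_path):
        path = tmp_path / "fix.GENN.dx"
        path.write_text(HANDCRAFTED_DX)
        g = read_gfe_map(path, gfe_cap=10.0)
        assert g.map_type == "GENN"
        assert g.dims == (2, 2, 2)
        np.testing.assert_array_equal(g.origin, np.zeros(3))
        np.testing.assert_array_equal(g.spacing, np.ones(3))
        # z-fastest: flat order (0,0,0),(0,0,1),(0,1,0),(0,1,1),(1,0,0)...
        np.testing.assert_array_equal(g.values.reshape(-1), np.arange(8.0))
        assert g.values[1, 0, 1] == 5.0

    def test_round_trip_identity(self, tmp_path, random_grid):
        path = tmp_path / "rt.GENN.dx"
        write_gfe_map(random_grid, path)
        back = read_gfe_map(path)
        np.testing.assert_array_equal(back.values, random_grid.values)
        np.testing.assert_array_equal(back.origin, random_grid.origin)
        np.testing.assert_array_equal(back.spacing, random_grid.spacing)
        assert back.map_type == random_grid.map_type

    def test_value_count_mismatch_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.GENN.dx"
        path.write_text(HANDCRAFTED_DX.replace("6.0 7.0\n", "6.0\n"))
        with pytest.raises(GridParseError, match="7 data values for 8 voxels"):
            read_gfe_map(path)

    def test_malformed_header_names_line(self, tmp_path):
        path = tmp_path / "bad2.GENN.dx"
        path.write_text(HANDCRAFTED_DX.replace("counts 2 2 2\norigin", "counts 2 2\norigin", 1))
        with pytest.raises(GridParseError, match="gridpositions"):
            read_gfe_map(path)

    def test_map_type_from_filename_convention(self, tmp_path, random_grid):
        path = tmp_path / "herg.MAMN.dx"
        write_gfe_map(random_grid, path)
        assert read_gfe_map(path).map_type == "MAMN"
        assert read_gfe_map(path, map_type="XYZ").map_type == "XYZ"
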