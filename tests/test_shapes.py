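"""Shape synthesis: prephonatory surfaces, modal superposition, contact,
extrusion and corpus enumeration."""

import numpy as np
import pytest

from glottiflow import (
    PrephonatoryParams,
    ShapeSpec,
    VibrationMode,
    build_channel,
    build_prephonatory,
    discretize_channel,
    enumerate_shape_set,
    extrude_airway,
    modal_displacement,
    resolve_contact,
    superimpose,
)
from glottiflow.shapes import (
    InvalidParameterError,
    channel_to_gap_csv,
    channel_to_mesh,
)


def untapered(surface, params):
    """z-indices inside the untapered span of the fold."""
    L = params.fold_length_L
    return (surface.z_grid > 0.05 * L + 1e-9) & (surface.z_grid < 0.95 * L - 1e-9)


class TestPrephonatory:
    def test_uniform_half_gaps_give_rectangular_glottis(self):
        p = PrephonatoryParams(half_gap_inferior=0.05, half_gap_superior=0.05)
        s = build_prephonatory(p)
        gap = s.x_right - s.x_left
        assert np.allclose(gap[:, untapered(s, p)], 0.1)

    def test_convergent_linear_interpolation_midpoint(self, convergent_params):
        s = build_prephonatory(convergent_params)
        iy = np.argmin(np.abs(s.y_grid - 0.15))
        mid = s.half_gap[iy, untapered(s, convergent_params)]
        assert np.allclose(mid, 0.06)

    def test_surface_extents_match_fold_dimensions(self):
        p = PrephonatoryParams(initial_half_gap_dx=0.002)
        s = build_prephonatory(p)
        assert s.z_grid[0] == 0.0 and s.z_grid[-1] == pytest.approx(1.5)
        assert s.y_grid[0] == 0.0 and s.y_grid[-1] == pytest.approx(0.3)

    def test_mirror_symmetry(self, convergent_params):
        s = build_prephonatory(convergent_params)
        assert np.allclose(s.x_left, -s.x_right)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fold_length_L": -1.0},
            {"medial_thickness_T": 0.0},
            {"half_gap_inferior": -0.01},
            {"mesh_resolution": 0.1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            PrephonatoryParams(**kwargs)


class TestModalDisplacement:
    def test_vanishes_at_anterior_posterior_ends(self):
        mode = VibrationMode(2, 1, 0.07)
        for z in (0.0, 1.5):
            assert modal_displacement(mode, 0.1, z, 1.3, L=1.5, T=0.3) == pytest.approx(0.0)

    def test_fundamental_mode_midpoint_amplitude(self):
        mode = VibrationMode(1, 0, 0.04)
        val = modal_displacement(mode, 0.12, 0.75, 0.0, L=1.5, T=0.3)
        assert val == pytest.approx(0.04)

    def test_mode_11_quarter_phase_reduces_to_sine_profile(self):
        a, L, T = 0.03, 1.5, 0.3
        mode = VibrationMode(1, 1, a)
        z = np.linspace(0, L, 7)
        val = modal_displacement(mode, T / 2, z, np.pi / 2, L=L, T=T)
        assert np.allclose(val, a * np.sin(np.pi * z / L))


class TestSuperimpose:
    def test_zero_amplitude_reduces_to_prephonatory(self, convergent_params):
        spec = ShapeSpec(convergent_params, (VibrationMode(1, 0, 0.0),), 1.0)
        s = superimpose(spec)
        s0 = build_prephonatory(convergent_params)
        assert np.allclose(s.x_right, s0.x_right)
        assert np.allclose(s.x_left, s0.x_left)

    def test_phase_periodicity(self, convergent_params):
        modes = (VibrationMode(1, 1, 0.05),)
        a = superimpose(ShapeSpec(convergent_params, modes, 0.7))
        b = superimpose(ShapeSpec(convergent_params, modes, 0.7 + 2 * np.pi))
        assert np.max(np.abs(a.x_right - b.x_right)) < 1e-12

    def test_large_amplitude_interpenetrates_before_contact(self):
        p = PrephonatoryParams(half_gap_inferior=0.02, half_gap_superior=0.02)
        # at phase pi the (1, 0) mode displacement is -a sin(pi z / L)
        spec = ShapeSpec(p, (VibrationMode(1, 0, 0.1),), np.pi)
        s = superimpose(spec)
        assert np.any(s.x_left > s.x_right)

    def test_gap_perturbation_anchored_at_fold_ends(self, divergent_params):
        spec = ShapeSpec(divergent_params, (VibrationMode(1, 1, 0.08),), 2.2)
        s = superimpose(spec)
        s0 = build_prephonatory(divergent_params)
        for j in (0, -1):
            assert np.allclose(s.x_right[:, j], s0.x_right[:, j], atol=1e-14)


class TestResolveContact:
    def test_identity_without_interpenetration(self, convergent_params):
        s = build_prephonatory(convergent_params)
        r = resolve_contact(s)
        assert np.array_equal(r.x_right, s.x_right)

    def test_pointwise_arithmetic_mean(self):
        p = PrephonatoryParams()
        s = build_prephonatory(p)
        s.x_left[3, 5], s.x_right[3, 5] = 0.05, 0.03
        r = resolve_contact(s)
        assert r.x_left[3, 5] == pytest.approx(0.04)
        assert r.x_right[3, 5] == pytest.approx(0.04)

    def test_closed_phase_gap_is_exactly_zero_on_contact_patch(self):
        p = PrephonatoryParams(half_gap_inferior=0.02, half_gap_superior=0.02)
        spec = ShapeSpec(p, (VibrationMode(1, 0, 0.1),), np.pi)
        r = resolve_contact(superimpose(spec))
        gap = r.x_right - r.x_left
        assert gap.min() == 0.0
        assert np.all(gap >= 0.0)


class TestExtrude:
    def test_zero_length_parts_give_glottis_alone(self, convergent_params):
        from dataclasses import replace

        p = replace(
            convergent_params, contraction_length_Lc=0.0, expansion_length_Le=0.0
        )
        s = resolve_contact(build_prephonatory(p))
        ch = extrude_airway(s, p)
        assert np.all(ch.part_labels == "glottis")
        assert np.allclose(ch.gap_field, s.half_gap)

    def test_matched_inlet_gives_straight_contraction(self):
        p = PrephonatoryParams(
            half_gap_inferior=0.05,
            half_gap_superior=0.02,
            contraction_inlet_halfwidth=0.05,
        )
        s = resolve_contact(build_prephonatory(p))
        ch = extrude_airway(s, p)
        contraction = ch.part_labels == "contraction"
        j = np.argmin(np.abs(ch.z_grid - 0.75))  # untapered mid-fold column
        assert np.allclose(ch.gap_field[contraction, j], 0.05)

    def test_inlet_area_exceeds_every_glottal_area(self, convergent_params):
        ch = build_channel(ShapeSpec(convergent_params, (VibrationMode(1, 1, 0.02),), 0.4))
        d = discretize_channel(ch, 64)
        assert d.inlet_area_As > d.A[1:].max()


class TestEnumeration:
    @pytest.mark.parametrize(
        "n_pre, n_modes, n_phases, expected",
        [(2, 2, 16, 64), (1, 1, 1, 1), (2, 2, 4, 16)],
    )
    def test_counts_are_cartesian_products(
        self, convergent_params, divergent_params, n_pre, n_modes, n_phases, expected
    ):
        pres = [convergent_params, divergent_params][:n_pre]
        modes = [VibrationMode(1, 0, 0.05), VibrationMode(1, 1, 0.02)][:n_modes]
        channels = enumerate_shape_set(pres, modes, n_phases)
        assert len(channels) == expected

    def test_empty_lists_rejected(self, convergent_params):
        with pytest.raises(InvalidParameterError):
            enumerate_shape_set([], [VibrationMode()], 4)
        with pytest.raises(InvalidParameterError):
            enumerate_shape_set([convergent_params], [], 4)


class TestExport:
    def test_gap_csv_round_trip(self, tmp_path, convergent_params):
        import pandas as pd

        ch = build_channel(ShapeSpec(convergent_params, (), 0.0))
        path = tmp_path / "gap.csv"
        channel_to_gap_csv(ch, path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["y_cm", "z_cm", "gap_cm"]
        assert len(df) == ch.gap_field.size
        assert df["gap_cm"].max() == pytest.approx(2 * ch.gap_field.max())

    def test_mesh_export_formats(self, tmp_path, convergent_params):
        ch = build_channel(ShapeSpec(convergent_params, (), 0.0))
        vtk = tmp_path / "shape.vtk"
        channel_to_mesh(ch, vtk)
        assert vtk.read_text().startswith("# vtk DataFile")
        stl = tmp_path / "shape.stl"
        channel_to_mesh(ch, stl)
        assert stl.stat().st_size > 0
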