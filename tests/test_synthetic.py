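"""Tests for the synthetic population and tile generator."""

import numpy as np
import pytest
from scipy.stats import kstest

import cycleprof.synthetic as syn
from cycleprof.errors import ValidationError

from conftest import make_spec


class TestPopulationSampling:
    def test_empty_population(self, params):
        assert syn.sample_population(params, syn.preset("constant"), 0, seed=1) == []

    def test_negative_n_rejected(self, params):
        with pytest.raises(ValidationError):
            syn.sample_population(params, syn.preset("constant"), -1, seed=1)

    def test_length_distribution_matches_steady_state_cdf(self, params):
        """Empirical lengths follow the closed-form CDF obtained by pushing
        the extant-age density through the tip-growth map (KS < 0.01)."""
        specs = syn.sample_population(params, syn.preset("constant"), 50_000, seed=1)
        lengths = np.array([s.length for s in specs])
        res = kstest(lengths, lambda l: syn.length_cdf(l, params))
        assert res.statistic < 0.01

    def test_septated_cells_exceed_mitotic_entry_length(self, params):
        specs = syn.sample_population(params, syn.preset("constant"), 5000, seed=3)
        sept = [s for s in specs if s.stage is syn.Stage.SEPTATED]
        assert sept and all(s.length > params.mitotic_entry_length for s in sept)

    def test_length_histogram_youngest_heavy(self, params):
        """A steady exponential culture has more young (short) than old
        (long) cells: histogram counts decay with length up to counting
        noise."""
        specs = syn.sample_population(params, syn.preset("constant"), 20_000, seed=4)
        lengths = [s.length for s in specs]
        h, _ = np.histogram(lengths, bins=10,
                            range=(params.birth_length, params.division_length))
        assert np.all(np.diff(h) <= 2.0 * np.sqrt(h[:-1]))

    def test_stage_counts_and_nucleus_multiplicity(self, params):
        specs = syn.sample_population(params, syn.preset("constant"), 5000, seed=5)
        for s in specs:
            expected = 2 if s.stage in (syn.Stage.BINUCLEATE, syn.Stage.SEPTATED) else 1
            assert len(s.nucleus_centers) == expected

    def test_seed_determinism(self, params):
        a = syn.sample_population(params, syn.preset("cdc13"), 200, seed=42)
        b = syn.sample_population(params, syn.preset("cdc13"), 200, seed=42)
        assert a == b
        ta = syn.render_tile(a[0], params)
        tb = syn.render_tile(b[0], params)
        assert np.array_equal(ta.protein, tb.protein)
        noisy_a = syn.apply_noise(ta, a[0], syn.NoiseParams(seed=9))
        noisy_b = syn.apply_noise(tb, b[0], syn.NoiseParams(seed=9))
        assert np.array_equal(noisy_a.protein, noisy_b.protein)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            syn.PopulationParams(birth_length=13.0)  # birth > mitotic entry
        with pytest.raises(ValidationError):
            syn.PopulationParams(nuclear_area_fraction=1.5)
        with pytest.raises(ValidationError):
            syn.PopulationParams(division_length=16.0)  # not ~2x birth


class TestConcentrationModels:
    def test_constant_returns_baseline_everywhere(self):
        m = syn.preset("constant")
        for p in (0.0, 0.3, 1.0):
            c, n = syn.concentration_at(m, p)
            assert c == m.baseline_conc and n == c

    def test_linear_accumulator_endpoint_ratio(self):
        m = syn.StrainProfileModel(syn.ProfileKind.LINEAR_ACCUMULATOR,
                                   wholecell_fold=4.5)
        c0, _ = syn.concentration_at(m, 0.0)
        c1, _ = syn.concentration_at(m, 1.0)
        assert c1 / c0 == pytest.approx(4.5)

    def test_oscillator_minimum_at_trough_position(self):
        """Grid search over a fine cycle grid locates the whole-cell
        minimum at the configured trough position."""
        m = syn.StrainProfileModel(syn.ProfileKind.OSCILLATOR,
                                   wholecell_fold=2.0, trough_position=1 / 3)
        grid = np.linspace(0, 1, 3001)
        c = syn.wholecell_concentration(m, grid)
        assert grid[np.argmin(c)] == pytest.approx(1 / 3, abs=2e-3)

    def test_g1s_pulse_monotone_nonincreasing_through_g2(self):
        m = syn.preset("cdc18")
        grid = np.linspace(0, 0.75, 500)
        c = syn.wholecell_concentration(m, grid)
        assert np.all(np.diff(c) <= 1e-9)
        assert syn.wholecell_concentration(m, 0.0) == pytest.approx(
            m.baseline_conc * m.wholecell_fold)

    def test_nuclear_value_is_enrichment_times_wholecell(self):
        m = syn.preset("cdc2")
        c, n = syn.concentration_at(m, 0.5)
        assert n == pytest.approx(c * m.enrichment_at(0.5))

    def test_cycle_position_out_of_range(self):
        with pytest.raises(ValidationError):
            syn.concentration_at(syn.preset("constant"), 1.2)

    def test_constant_kind_requires_fold_one(self):
        with pytest.raises(ValidationError):
            syn.StrainProfileModel(syn.ProfileKind.CONSTANT, wholecell_fold=2.0)


class TestRendering:
    def test_zero_concentration_gives_blank_protein(self, params):
        spec = make_spec(conc=0.0, enrichment=0.0)
        tile = syn.render_tile(spec, params)
        assert np.all(tile.protein == 0.0)

    @pytest.mark.parametrize("stage,p", [
        (syn.Stage.G2_MONO, 0.3), (syn.Stage.MITOTIC_MONO, 0.8),
        (syn.Stage.BINUCLEATE, 0.87), (syn.Stage.SEPTATED, 0.95),
    ])
    def test_pixel_sum_bookkeeping(self, params, stage, p):
        """Noise-free protein sums obey both the cytoplasm/nucleus mixture
        formula and total conservation (sum = conc x cell area)."""
        length = syn.length_at(p, params)
        spec = make_spec(length=length, stage=stage, p=p, conc=80.0,
                         enrichment=1.8, params=params)
        tile = syn.render_tile(spec, params)
        a = tile.cell_mask.sum()
        an = tile.nuclear_mask.sum()
        cyto = (spec.true_wholecell_conc * a - spec.true_nuclear_conc * an) / (a - an)
        expected = cyto * (a - an) + spec.true_nuclear_conc * an
        assert tile.protein.sum() == pytest.approx(expected, abs=1.0)
        assert tile.protein.sum() == pytest.approx(spec.true_wholecell_conc * a,
                                                   abs=1.0)

    def test_rendered_nuclear_area_fraction(self, params):
        """The nuclear disk occupies ~15% of the projected cell area."""
        specs = syn.sample_population(params, syn.preset("constant"), 100, seed=6)
        fracs = [syn.render_tile(s, params).nuclear_mask.sum()
                 / syn.render_tile(s, params).cell_mask.sum()
                 for s in specs if s.stage is syn.Stage.G2_MONO]
        assert np.mean(fracs) == pytest.approx(0.15, abs=0.02)

    def test_nucleus_outside_rod_rejected(self, params):
        with pytest.raises(ValidationError):
            spec = syn.CellSpec(length=8.0, stage=syn.Stage.G2_MONO,
                                cycle_position=0.1, nucleus_centers=(4.0,),
                                nucleus_radius=2.5, true_wholecell_conc=1.0,
                                true_nuclear_conc=1.0)
            syn.render_tile(spec, params)

    def test_over_enriched_nucleus_rejected(self, params):
        spec = make_spec(conc=100.0, enrichment=8.0)  # 8 x 0.15 > 1
        with pytest.raises(ValidationError):
            syn.render_tile(spec, params)

    def test_marker_confined_to_nuclei(self, params):
        tile = syn.render_tile(make_spec(), params)
        assert np.all(tile.marker[~tile.nuclear_mask] == 0)
        assert np.all(tile.marker[tile.nuclear_mask] > 0)

    def test_channels_share_shape_and_are_nonnegative(self, params):
        tile = syn.render_tile(make_spec(), params)
        assert tile.protein.shape == tile.marker.shape == tile.bf.shape
        for ch in (tile.protein, tile.marker, tile.bf):
            assert np.all(ch >= 0)


class TestNoise:
    def test_noise_free_configuration_is_identity(self, params):
        spec = make_spec()
        tile = syn.render_tile(spec, params)
        nz = syn.NoiseParams(autofluor_intercept=0, autofluor_slope=0,
                             read_noise_sd=0, shot_noise=False, seed=1)
        out = syn.apply_noise(tile, spec, nz)
        assert np.array_equal(out.protein, tile.protein)
        assert np.array_equal(out.bf, tile.bf)

    def test_autofluorescence_is_linear_in_length(self, params):
        """b0=2, b1=0.5 on a 10-um cell with no protein -> mean in-cell
        intensity of 7."""
        spec = make_spec(length=10.0, conc=0.0, enrichment=0.0)
        tile = syn.render_tile(spec, params)
        nz = syn.NoiseParams(autofluor_intercept=2.0, autofluor_slope=0.5,
                             autofluor_cv=0.0, read_noise_sd=0,
                             shot_noise=False, seed=1)
        out = syn.apply_noise(tile, spec, nz)
        assert out.protein[tile.cell_mask].mean() == pytest.approx(7.0)

    def test_shot_noise_poisson_variance(self, params):
        """Poisson resampling of a constant-100 image gives per-pixel
        variance ~=100 over >=1e4 pixels."""
        img = np.full((150, 150), 100.0)
        tile = syn.ImageTile(protein=img.copy(), marker=np.zeros_like(img),
                             bf=np.full_like(img, 100.0), pixel_size=0.1,
                             cell_mask=np.ones_like(img, dtype=bool))
        spec = make_spec(length=10.0)
        nz = syn.NoiseParams(autofluor_intercept=0, autofluor_slope=0,
                             read_noise_sd=0, shot_noise=True, seed=2)
        out = syn.apply_noise(tile, spec, nz)
        assert out.protein.var() == pytest.approx(100.0, rel=0.05)
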