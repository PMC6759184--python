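"""Tests of the dual-reporter surrogate movie generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from clockloops import rhythms
from clockloops.surrogate import (
    CellField,
    MovieStack,
    SurrogateConfig,
    cell_signal,
    generate_surrogate,
    load_surrogate,
    place_cells,
    render_movie,
)


@pytest.mark.parametrize(
    "intensity,period,phase,t,expected",
    [
        (1.0, 24.0, 0.0, 0.0, 1.0),
        (1.0, 24.0, 0.0, 12.0, 0.0),
        (2.0, 24.0, 0.0, 6.0, 1.0),
        # brute-force evaluation of I/2*(1+cos(2*pi*t/tau + phi))
        (1.0, 23.0, np.pi / 2, 5.75,
         0.5 * (1 + np.cos(2 * np.pi * 5.75 / 23.0 + np.pi / 2))),
    ],
)
def test_cell_signal_formula(intensity, period, phase, t, expected):
    assert cell_signal(intensity, period, phase, t) == pytest.approx(expected, abs=1e-12)


def test_cell_signal_bounded_and_rejects_bad_period():
    t = np.linspace(0, 100, 1000)
    s = cell_signal(1.5, 23.0, 1.0, t)
    assert s.min() >= 0 and s.max() <= 1.5
    with pytest.raises(ValueError):
        cell_signal(1.0, -1.0, 0.0, 0.0)


def test_config_validation():
    with pytest.raises(ValueError):
        SurrogateConfig(hypothesis="H0_3")
    with pytest.raises(ValueError):
        SurrogateConfig(n_cells=0)
    with pytest.raises(ValueError):
        SurrogateConfig(layer_attenuation=0.0)


class TestPlaceCells:
    def test_dual_reporter_cells_carry_both_channels(self):
        cfg = SurrogateConfig(n_cells=150, hypothesis="H0_1", n_layers=1)
        field = place_cells(cfg)
        df = field.layers[0]
        assert len(df) == 150
        assert (df["channel"] == "both").all()
        assert (df["period_bmal"] == 23.0).all()
        assert (df["period_per"] == 24.0).all()

    @pytest.mark.parametrize("n,expected_bmal", [(2, 1), (5, 3)])
    def test_single_reporter_split(self, n, expected_bmal):
        cfg = SurrogateConfig(n_cells=n, hypothesis="H0_2", n_layers=2)
        field = place_cells(cfg)
        for df in field.layers:
            assert (df["channel"] == "bmal").sum() == expected_bmal
            assert (df["channel"] == "per").sum() == n - expected_bmal
            # single-reporter cells carry exactly one period
            assert df["period_bmal"].notna().sum() == expected_bmal

    def test_deterministic_under_seed(self):
        cfg = SurrogateConfig(n_cells=20, seed=3, n_layers=2)
        f1, f2 = place_cells(cfg), place_cells(cfg)
        for a, b in zip(f1.layers, f2.layers):
            pd.testing.assert_frame_equal(a, b)

    def test_positions_do_not_depend_on_hypothesis(self):
        c1 = SurrogateConfig(n_cells=30, hypothesis="H0_1", seed=5)
        c2 = dataclasses.replace(c1, hypothesis="H0_2")
        f1, f2 = place_cells(c1), place_cells(c2)
        for a, b in zip(f1.layers, f2.layers):
            np.testing.assert_array_equal(a[["x", "y"]], b[["x", "y"]])

    def test_layers_are_independent_draws(self):
        cfg = SurrogateConfig(n_cells=10, seed=1, n_layers=2)
        f = place_cells(cfg)
        assert not np.allclose(f.layers[0]["x"], f.layers[1]["x"])

    def test_common_phase_mode(self):
        cfg = SurrogateConfig(n_cells=8, phase_mode="common", n_layers=1)
        df = place_cells(cfg).layers[0]
        assert (df["phase_bmal"] == 0).all() and (df["phase_per"] == 0).all()


def _single_cell_field(x=0.5, y=0.5, phase=0.0, n_layers=1, period=24.0):
    layer = pd.DataFrame(
        {
            "x": [x], "y": [y], "intensity": [1.0], "channel": ["both"],
            "period_bmal": [period], "period_per": [period],
            "phase_bmal": [phase], "phase_per": [phase],
        }
    )
    return CellField(layers=tuple(layer.copy() for _ in range(n_layers)),
                     hypothesis="H0_1")


class TestRenderMovie:
    def test_frame_count_matches_duration(self):
        cfg = SurrogateConfig(n_cells=1, duration_days=1.0, dt=1.0,
                              grid_shape=(16, 16), sigma_n=0.0)
        b, p = render_movie(place_cells(cfg), cfg)
        assert b.frames.shape[0] == 25 == b.times.size

    def test_reference_duration_gives_289_frames(self):
        cfg = SurrogateConfig(n_cells=1, grid_shape=(16, 16), sigma_n=0.0)
        b, _ = render_movie(place_cells(cfg), cfg)
        assert b.frames.shape[0] == 289

    def test_trough_frame_is_zero_without_noise(self):
        # cos peak at t=0 with phase 0 -> trough at t = tau/2 = 12 h
        cfg = SurrogateConfig(n_cells=1, sigma_n=0.0, dt=12.0, duration_days=1.0,
                              grid_shape=(32, 32))
        field = _single_cell_field(phase=0.0)
        b, _ = render_movie(field, cfg)
        assert b.times[1] == 12.0
        assert np.allclose(b.frames[1], 0.0, atol=1e-12)

    def test_three_identical_layers_sum_to_1p75(self):
        cfg1 = SurrogateConfig(n_cells=1, sigma_n=0.0, dt=24.0, duration_days=1.0,
                               grid_shape=(32, 32), n_layers=1)
        cfg3 = dataclasses.replace(cfg1, n_layers=3)
        f1 = _single_cell_field(n_layers=1)
        f3 = _single_cell_field(n_layers=3)
        b1, _ = render_movie(f1, cfg1)
        b3, _ = render_movie(f3, cfg3)
        np.testing.assert_allclose(b3.frames, 1.75 * b1.frames, rtol=1e-12)

    def test_prenoise_linearity_in_intensity(self):
        cfg = SurrogateConfig(n_cells=6, sigma_n=0.0, duration_days=1.0,
                              grid_shape=(32, 32), seed=2)
        cfg2 = dataclasses.replace(cfg, intensity=2.0)
        b1, _ = render_movie(place_cells(cfg), cfg)
        b2, _ = render_movie(place_cells(cfg2), cfg2)
        np.testing.assert_allclose(b2.frames, 2 * b1.frames, rtol=1e-12)

    def test_frame_mass_matches_bruteforce_rasterization(self):
        """Total pre-noise mass equals a naive per-cell, per-pixel summation."""
        cfg = SurrogateConfig(n_cells=3, sigma_n=0.0, dt=24.0, duration_days=1.0,
                              grid_shape=(24, 24), seed=9, n_layers=2)
        field = place_cells(cfg)
        b, _ = render_movie(field, cfg)
        nr, nc = cfg.grid_shape
        sigma_px = cfg.sigma_g * nc
        rows = np.arange(nr) + 0.5
        cols = np.arange(nc) + 0.5
        for k, t in enumerate(b.times):
            expected = np.zeros((nr, nc))
            for li, df in enumerate(field.layers):
                w_layer = cfg.layer_attenuation**li
                for rec in df.itertuples(index=False):
                    s = cell_signal(rec.intensity, rec.period_bmal,
                                    rec.phase_bmal, t)
                    dr = rows[:, None] - rec.y * nr
                    dc = cols[None, :] - rec.x * nc
                    g = np.exp(-(dr**2 + dc**2) / (2 * sigma_px**2))
                    expected += cfg.kernel_gain * s * w_layer * g
            # the renderer truncates the kernel at +-4 sigma (<1e-4 mass)
            assert b.frames[k].sum() == pytest.approx(expected.sum(), rel=1e-3)

    def test_time_average_is_phase_independent_mean_field(self):
        # with an integer number of cycles the cosine averages out exactly,
        # leaving each blob at gain * I/2
        cfg = SurrogateConfig(n_cells=3, sigma_n=0.0, n_layers=1, seed=4,
                              period_bmal=24.0, period_per=24.0,
                              duration_days=10.0, grid_shape=(32, 32))
        field = place_cells(cfg)
        b, _ = render_movie(field, cfg)
        mean_frame = b.frames[:-1].mean(axis=0)  # 240 samples = 10 cycles
        static = np.zeros_like(mean_frame)
        nr, nc = cfg.grid_shape
        sigma_px = cfg.sigma_g * nc
        rows = np.arange(nr) + 0.5
        cols = np.arange(nc) + 0.5
        for rec in field.layers[0].itertuples(index=False):
            dr = rows[:, None] - rec.y * nr
            dc = cols[None, :] - rec.x * nc
            static += (cfg.kernel_gain * rec.intensity / 2
                       * np.exp(-(dr**2 + dc**2) / (2 * sigma_px**2)))
        assert np.abs(mean_frame - static).max() < 1e-10 + 1e-3 * static.max()


class TestGenerateSurrogate:
    def test_bit_identical_over_reruns(self, small_config):
        b1, p1 = generate_surrogate(small_config)
        b2, p2 = generate_surrogate(small_config)
        np.testing.assert_array_equal(b1.frames, b2.frames)
        np.testing.assert_array_equal(p1.frames, p2.frames)

    def test_roundtrip_npz(self, small_config, tmp_path):
        b, p = generate_surrogate(small_config, out_dir=tmp_path)
        b2, p2, meta = load_surrogate(tmp_path / "surrogate.npz")
        np.testing.assert_array_equal(b.frames, b2.frames)
        assert meta["config"]["n_cells"] == small_config.n_cells
        assert (tmp_path / "surrogate_config.yaml").exists()

    def test_noise_free_channel_periods_recovered(self, analysis_config):
        """Pixel-wise Lomb-Scargle on a noise-free stack recovers 23 h and
        24 h at every cell-covered pixel."""
        cfg = SurrogateConfig(n_cells=5, sigma_n=0.0, grid_shape=(32, 32),
                              seed=11, n_layers=2)
        b, p = generate_surrogate(cfg)
        covered = b.frames.max(axis=0) > 0.05 * cfg.kernel_gain
        mb = rhythms.pixelwise_period_map(b, analysis_config)
        mp = rhythms.pixelwise_period_map(p, analysis_config)
        assert mb.shape == cfg.grid_shape
        assert np.all(np.abs(mb[covered] - 23.0) < 0.2)
        assert np.all(np.abs(mp[covered] - 24.0) < 0.2)
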