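"""Track generator and time-lapse behaviour statistics."""
import numpy as np
import pandas as pd
import pytest

from iridoptics import (
    TrackGeneratorParams,
    division_angle_stats,
    generate_tracks,
    migration_bias,
    proliferation_rates,
)
from iridoptics.cell_dynamics import TrackDataset
from iridoptics.errors import DataError, ParameterError


def short_params(**kw):
    defaults = dict(duration_h=2.0)
    defaults.update(kw)
    return TrackGeneratorParams(**defaults)


class TestGenerator:
    def test_zero_drift_zero_jitter_is_static(self):
        p = short_params(dense_jitter_um=0.0, loose_jitter_um=0.0,
                         loose_drift_um_per_frame=(0.0, 0.0))
        ds = generate_tracks(5, 5, p, rng_seed=0)
        for _, g in ds.tracks.groupby("cell_id"):
            assert g["x_um"].nunique() == 1
            assert g["y_um"].nunique() == 1

    def test_infinite_kappa_gives_exact_ap_angles(self):
        p = short_params(kappa_dense=np.inf, division_rate_dense=2.0)
        ds = generate_tracks(50, 0, p, rng_seed=1)
        dense_angles = ds.divisions["angle_deg"].to_numpy()
        assert dense_angles.size > 0
        assert (dense_angles == 0.0).all()

    def test_seeded_regeneration_bit_identical(self):
        a = generate_tracks(10, 10, short_params(), rng_seed=42)
        b = generate_tracks(10, 10, short_params(), rng_seed=42)
        pd.testing.assert_frame_equal(a.tracks, b.tracks)
        pd.testing.assert_frame_equal(a.divisions, b.divisions)

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            generate_tracks(-1, 0)

    def test_timestamps_strictly_increasing_enforced(self):
        tracks = pd.DataFrame({
            "cell_id": [0, 0], "class": ["dense", "dense"],
            "t": [5.0, 5.0], "x_um": [0.0, 0.0], "y_um": [0.0, 0.0],
        })
        with pytest.raises(DataError):
            TrackDataset(tracks)


class TestDivisionAngles:
    def test_concentrated_angles(self):
        s = division_angle_stats([0.0, 0.0, 0.0])
        assert s.mean_axis_deg == 0.0
        assert s.resultant_length == pytest.approx(1.0)

    def test_perpendicular_pair_cancels(self):
        # doubled angles are antipodal, so the resultant vanishes
        s = division_angle_stats([0.0, 90.0])
        assert s.resultant_length == pytest.approx(0.0, abs=1e-12)

    def test_axial_wraparound_mean(self):
        # 170 and 10 degrees straddle the AP axis; the mean axis is 0
        s = division_angle_stats([170.0, 10.0])
        assert min(s.mean_axis_deg, 180.0 - s.mean_axis_deg) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_angles_not_rejected(self):
        rng = np.random.default_rng(3)
        s = division_angle_stats(rng.uniform(0, 180, 500))
        assert s.p_uniform > 0.05

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            division_angle_stats([])

    def test_rayleigh_p_matches_closed_form(self):
        # Zar's approximation: z = n * rbar^2,
        # p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)) with R = n*rbar
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 180, 60)
        s = division_angle_stats(a)
        n = a.size
        R = n * s.resultant_length
        p_oracle = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - R**2)) - (1 + 2 * n))
        assert s.p_uniform == pytest.approx(p_oracle, rel=1e-6)


class TestMigration:
    def test_all_static_dataset_has_no_qualifying_cells(self):
        p = short_params(loose_jitter_um=0.0, loose_drift_um_per_frame=(0.0, 0.0))
        ds = generate_tracks(0, 10, p, rng_seed=0)
        rep = migration_bias(ds, "loose", 20.0)
        assert rep.empty and rep.n_qualifying == 0

    def test_ventral_drift_detected(self):
        p = short_params(loose_drift_um_per_frame=(0.0, -5.0), loose_jitter_um=2.0)
        ds = generate_tracks(0, 50, p, rng_seed=1)
        rep = migration_bias(ds, "loose", 20.0, rng_seed=1)
        assert rep.mean_dv_um < 0
        assert rep.ci_high_um < 0
        assert rep.fraction_away_from_interstripe > 0.9

    def test_translation_invariance(self):
        p = short_params(loose_drift_um_per_frame=(0.0, -2.0))
        ds = generate_tracks(0, 20, p, rng_seed=2)
        shifted = TrackDataset(
            ds.tracks.assign(x_um=ds.tracks["x_um"] + 1000.0,
                             y_um=ds.tracks["y_um"] - 500.0),
            ds.divisions,
        )
        a = migration_bias(ds, "loose", 10.0, rng_seed=0)
        b = migration_bias(shifted, "loose", 10.0, rng_seed=0)
        assert a.mean_dv_um == pytest.approx(b.mean_dv_um)
        assert a.n_qualifying == b.n_qualifying

    def test_unknown_class_rejected(self):
        ds = generate_tracks(2, 2, short_params(), rng_seed=0)
        with pytest.raises(ParameterError):
            migration_bias(ds, "sparse")


class TestProliferation:
    def test_zero_divisions_rate_zero_with_exact_upper_ci(self):
        p = short_params(division_rate_dense=0.0, division_rate_loose=0.0)
        ds = generate_tracks(10, 10, p, rng_seed=0)
        rates = proliferation_rates(ds)
        for cls in ("dense", "loose"):
            r = rates["classes"][cls]
            assert r.n_divisions == 0
            assert r.rate_per_cell_hour == 0.0
            # exact Poisson upper bound for 0 events in T hours: 3.689/T
            assert r.ci_high == pytest.approx(3.6889 / r.cell_hours, rel=1e-3)

    def test_rates_invariant_to_splitting_a_track(self):
        p = short_params(division_rate_dense=0.5)
        ds = generate_tracks(5, 0, p, rng_seed=3)
        tracks = ds.tracks.copy()
        # split cell 0's track at its midpoint into two contiguous tracks
        cell0 = tracks[tracks["cell_id"] == 0]
        t_mid = cell0["t"].iloc[len(cell0) // 2]
        new_id = tracks["cell_id"].max() + 1
        # both halves share the boundary timepoint, so exposure is conserved
        second_half = cell0[cell0["t"] >= t_mid].assign(cell_id=new_id)
        tracks = pd.concat(
            [tracks[~((tracks["cell_id"] == 0) & (tracks["t"] > t_mid))], second_half],
            ignore_index=True,
        )
        divisions = ds.divisions.copy()
        divisions.loc[(divisions["cell_id"] == 0) & (divisions["t"] > t_mid), "cell_id"] = new_id
        split = TrackDataset(tracks, divisions)
        a = proliferation_rates(ds)["classes"]["dense"]
        b = proliferation_rates(split)["classes"]["dense"]
        assert a.n_divisions == b.n_divisions
        assert a.rate_per_cell_hour == pytest.approx(b.rate_per_cell_hour)

    def test_loose_exceeds_dense_at_generator_defaults(self):
        p = short_params(duration_h=5.0, division_rate_dense=0.05,
                         division_rate_loose=0.1)
        ds = generate_tracks(300, 300, p, rng_seed=4)
        rates = proliferation_rates(ds)
        assert (rates["classes"]["loose"].rate_per_cell_hour
                > rates["classes"]["dense"].rate_per_cell_hour)
        assert rates["loose_vs_dense"]["rate_ratio"] > 1.0
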