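import numpy as np
import pandas as pd
import pytest

from canaloflow import (aggregate_regions, build_mask, circumferential_profile,
                        downsample, fit_global, generate, normalize_percent)
from canaloflow.macropixels import MacropixelSeries
from canaloflow.synth import SectorKinetics
from conftest import make_small_spec


def small_series_and_mask(seed=0, noise_sd=0.0, **kw):
    spec = make_small_spec(seed=seed, noise_sd=noise_sd, **kw)
    stack, _ = generate(spec, grid_rows=16, grid_cols=16)
    series = normalize_percent(downsample(stack, 16, 16))
    return spec, series, build_mask(spec.geometry(), series)


class TestAggregateRegions:
    def test_uniform_intensity_gives_uniform_regions(self):
        spec = make_small_spec()
        stack, _ = generate(spec, grid_rows=16, grid_cols=16)
        series = downsample(stack, 16, 16)
        series.intensity[:] = 5.5
        pa = build_mask(spec.geometry(), series)
        regions = aggregate_regions(series, pa)
        non_empty = regions.table[regions.table["n_members"] > 0]
        np.testing.assert_allclose(non_empty["intensity"], 5.5)

    def test_single_hot_region(self):
        spec = make_small_spec()
        stack, _ = generate(spec, grid_rows=16, grid_cols=16)
        series = downsample(stack, 16, 16)
        series.intensity[:] = 0.0
        pa = build_mask(spec.geometry(), series)
        hot = pa.included & (pa.clock_hour == 3) & (pa.ring == 2)
        assert hot.any()
        series.intensity[:, hot] = 100.0
        regions = aggregate_regions(series, pa)
        t = regions.table
        hot_rows = t[(t["clock_hour"] == 3) & (t["ring"] == 2)]
        np.testing.assert_allclose(hot_rows["intensity"], 100.0)
        rest = t[((t["clock_hour"] != 3) | (t["ring"] != 2))
                 & (t["n_members"] > 0)]
        np.testing.assert_allclose(rest["intensity"], 0.0)

    def test_region_means_match_brute_force_groupby(self):
        _, series, pa = small_series_and_mask(seed=5, noise_sd=20.0)
        regions = aggregate_regions(series, pa)
        flat = series.intensity.reshape(series.n_frames, -1)
        for (h, r), grp in regions.table.groupby(["clock_hour", "ring"]):
            members = np.nonzero(pa.included.ravel()
                                 & (pa.clock_hour.ravel() == h)
                                 & (pa.ring.ravel() == r))[0]
            if members.size == 0:
                assert grp["intensity"].isna().all()
                continue
            expected = flat[:, members].mean(axis=1)
            np.testing.assert_allclose(
                grp.sort_values("frame")["intensity"].to_numpy(), expected,
                rtol=1e-12)

    def test_every_included_macropixel_in_exactly_one_region(self):
        _, series, pa = small_series_and_mask()
        regions = aggregate_regions(series, pa)
        per_region = regions.table.groupby(["clock_hour", "ring"])[
            "n_members"].first()
        assert per_region.sum() == pa.n_included
        assert regions.n_regions == 36


class TestFitGlobal:
    def test_region_table_has_36_rows(self, small_run):
        *_, result = small_run
        assert len(result.regional.region_table) == 36

    def test_identical_courses_give_equal_t_half(self):
        """All 36 regions sharing one logistic course must all recover
        the same half-max time to within one frame interval."""
        spec = make_small_spec(n_frames=20)
        stack, _ = generate(spec, grid_rows=16, grid_cols=16)
        series = downsample(stack, 16, 16)
        t = series.times_s
        series.intensity[:] = (100 / (1 + np.exp(-(t - 240) / 50.0)))[:, None, None]
        pa = build_mask(spec.geometry(), series)
        fit = fit_global(aggregate_regions(series, pa))
        th = fit.region_table.loc[~fit.region_table["empty"], "t_half_s"]
        assert th.max() - th.min() <= 30.0

    def test_ring_order_recovered_vs_individual_fits(self):
        """Ring 1 programmed to fill before ring 3; the global fit must
        order every clock hour's rings the same way as independent
        per-region curve fits do."""
        from canaloflow import fit_curve, extract_half_max

        spec = make_small_spec(n_frames=24)
        stack, _ = generate(spec, grid_rows=16, grid_cols=16)
        series = downsample(stack, 16, 16)
        t = series.times_s
        pa = build_mask(spec.geometry(), series)
        # radial gradient: inner ring fills at 240 s, outer at 600 s
        for r, t50 in ((1, 240.0), (2, 420.0), (3, 600.0)):
            m = pa.included & (pa.ring == r)
            series.intensity[:, m] = (100 / (1 + np.exp(-(t - t50) / 40.0)))[:, None]
        series.intensity[:, ~pa.included] = 0.0
        regions = aggregate_regions(series, pa)
        fit = fit_global(regions)
        tab = fit.region_table.set_index(["clock_hour", "ring"])
        for h in range(1, 13):
            if not (tab.loc[(h, 1), "empty"] or tab.loc[(h, 3), "empty"]):
                assert tab.loc[(h, 1), "t_half_s"] < tab.loc[(h, 3), "t_half_s"]
        # oracle: independent per-region fits agree within one interval
        for (h, r), grp in regions.table.groupby(["clock_hour", "ring"]):
            if grp["n_members"].iloc[0] == 0 or tab.loc[(h, r), "empty"]:
                continue
            y = grp.sort_values("frame")["intensity"].to_numpy()
            curve = fit_curve(t, y)
            _, _, t_ref = extract_half_max(curve, t[0], t[-1], 3.0)
            assert abs(tab.loc[(h, r), "t_half_s"] - t_ref) <= 30.0

    def test_cyclic_continuity_at_wraparound(self, small_run):
        *_, result = small_run
        for ring, surf in result.regional.surfaces.items():
            t = np.linspace(0, result.regional.times_s[-1], 7)
            np.testing.assert_allclose(surf(0.0, t), surf(12.0, t),
                                       rtol=0, atol=1e-8)

    def test_all_empty_regions_rejected(self):
        table = pd.DataFrame({"clock_hour": [1], "ring": [1], "frame": [0],
                              "time_s": [0.0], "intensity": [np.nan],
                              "n_members": [0]})
        from canaloflow.regional import RegionSeries
        rs = RegionSeries(table=table, times_s=np.arange(4) * 30.0,
                          frame_interval_s=30.0)
        with pytest.raises(ValueError, match="empty"):
            fit_global(rs)

    def test_rate_is_half_max_over_t_half(self, small_run):
        *_, result = small_run
        tab = result.regional.region_table
        ok = ~tab["empty"] & np.isfinite(tab["t_half_s"])
        np.testing.assert_allclose(
            tab.loc[ok, "filling_rate"],
            tab.loc[ok, "I_half"] / tab.loc[ok, "t_half_s"], rtol=1e-9)


class TestCircumferentialProfile:
    def test_profile_length_is_12(self, small_run):
        *_, result = small_run
        prof = circumferential_profile(result.regional)
        assert len(prof) == 12

    def test_rotationally_symmetric_eye_is_flat(self):
        spec = make_small_spec(sectors={
            q: SectorKinetics(1000.0, 200.0, 40.0, 10.0)
            for q in ("IN", "SN", "ST", "IT")})
        stack, _ = generate(spec, grid_rows=16, grid_cols=16)
        series = normalize_percent(downsample(stack, 16, 16))
        pa = build_mask(spec.geometry(), series)
        fit = fit_global(aggregate_regions(series, pa))
        prof = circumferential_profile(fit)
        th = prof["t_half_s"].dropna()
        assert th.max() - th.min() <= 30.0

    def test_fast_sector_is_profile_minimum(self):
        """One fast 3-hour sector: the profile's t_half minimum falls
        inside it."""
        spec = make_small_spec(n_frames=24, sector_mode="clock", sectors={
            h: (SectorKinetics(1000.0, 150.0, 30.0, 10.0) if h in (2, 3, 4)
                else SectorKinetics(1000.0, 450.0, 30.0, 10.0))
            for h in range(1, 13)})
        stack, _ = generate(spec, grid_rows=16, grid_cols=16)
        series = normalize_percent(downsample(stack, 16, 16))
        pa = build_mask(spec.geometry(), series)
        fit = fit_global(aggregate_regions(series, pa))
        prof = circumferential_profile(fit).dropna(subset=["t_half_s"])
        argmin_hour = int(prof.loc[prof["t_half_s"].idxmin(), "clock_hour"])
        assert argmin_hour in (2, 3, 4)
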