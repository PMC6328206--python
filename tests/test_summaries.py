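"""Behavioural classification, great-circle travel and seasonal products."""

import math

import numpy as np
import pandas as pd
import pytest

from dcrws.datasets import goc2001_track_summaries, goc2001_tracking_summary
from dcrws.summaries import (
    ARS,
    TRANSITING,
    UNCERTAIN,
    BehaviorThresholds,
    aggregate_tracks,
    assign_season,
    classify_mode,
    classify_track_locations,
    daily_steps,
    great_circle_km,
    per_track_summary,
    seasonal_mode_proportions,
)


# --- classification --------------------------------------------------------

@pytest.mark.parametrize("b, label", [
    (1.80, ARS), (1.20, TRANSITING),
    (1.50, UNCERTAIN), (1.25, UNCERTAIN), (1.75, UNCERTAIN),
    (1.0, TRANSITING), (2.0, ARS),
])
def test_classification_cutoffs(b, label):
    assert classify_mode(b) == label


def test_classification_partitions_unit_interval():
    for b in np.linspace(1.0, 2.0, 501):
        assert classify_mode(b) in {ARS, TRANSITING, UNCERTAIN}


def test_out_of_range_mode_rejected():
    with pytest.raises(ValueError):
        classify_mode(2.1)
    with pytest.raises(ValueError):
        BehaviorThresholds(ars_cutoff=1.2, transit_cutoff=1.5)


# --- great-circle distance -------------------------------------------------

def test_identical_points_zero():
    assert great_circle_km((-111.0, 26.0), (-111.0, 26.0)) == 0.0


def test_one_degree_meridian_arc():
    assert great_circle_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(
        2 * math.pi * 6371 / 360, rel=1e-9
    )


def test_antipodal_distance():
    assert great_circle_km((0.0, 0.0), (180.0, 0.0)) == pytest.approx(
        math.pi * 6371, rel=1e-9
    )


def test_symmetry_and_triangle_inequality():
    rng = np.random.default_rng(0)
    for _ in range(200):
        p = [(rng.uniform(-180, 180), rng.uniform(-90, 90)) for _ in range(3)]
        d01 = great_circle_km(p[0], p[1])
        assert d01 == pytest.approx(great_circle_km(p[1], p[0]), rel=1e-12)
        assert d01 <= great_circle_km(p[0], p[2]) + great_circle_km(p[2], p[1]) + 1e-9


# --- seasons ---------------------------------------------------------------

@pytest.mark.parametrize("date, season", [
    ("2001-03-26", "cool"), ("2001-07-23", "warm"), ("2001-12-01", "cool"),
    ("2001-06-01", "warm"), ("2001-11-30", "warm"), ("2002-05-31", "cool"),
])
def test_season_assignment(date, season):
    assert assign_season(date) == season


# --- daily steps -----------------------------------------------------------

def track_frame(lons, lats, b, start="2001-04-01"):
    n = len(lons)
    return pd.DataFrame({
        "date": pd.date_range(start, periods=n, tz="UTC"),
        "lon": lons, "lat": lats,
        "lon_hw95": 0.1, "lat_hw95": 0.1, "b_mean": b,
    })


def test_two_day_track_speed():
    # 24 km in one day -> 1 km/h
    lat_step = 24.0 / (2 * math.pi * 6371 / 360)
    df = track_frame([-111.0, -111.0], [26.0, 26.0 + lat_step], [1.1, 1.1])
    steps = daily_steps(df)
    assert len(steps) == 1
    assert steps["distance_km"].iloc[0] == pytest.approx(24.0, rel=1e-9)
    assert steps["speed_kmh"].iloc[0] == pytest.approx(1.0, rel=1e-9)


def test_constant_position_track():
    df = track_frame([-111.0] * 10, [26.0] * 10, [1.9] * 10)
    steps = daily_steps(df)
    assert len(steps) == 9
    assert (steps["distance_km"] == 0).all()


def test_steps_match_pairwise_haversine_oracle():
    rng = np.random.default_rng(1)
    lons = rng.uniform(-113, -110, 30)
    lats = rng.uniform(24, 31, 30)
    steps = daily_steps(track_frame(lons, lats, rng.uniform(1, 2, 30)))
    for i, row in steps.reset_index(drop=True).iterrows():
        d = great_circle_km((lons[i], lats[i]), (lons[i + 1], lats[i + 1]))
        assert row["distance_km"] == pytest.approx(d, rel=1e-12)
        assert row["speed_kmh"] == pytest.approx(d / 24.0, rel=1e-12)


def test_label_and_season_come_from_end_day():
    df = track_frame([-111.0, -111.2], [26.0, 26.3], [1.1, 1.9], start="2001-05-31")
    steps = daily_steps(df)
    assert steps["label"].iloc[0] == ARS  # end-day b = 1.9
    assert steps["season"].iloc[0] == "warm"  # end day lands in June


def test_gap_in_daily_grid_rejected():
    df = track_frame([-111.0, -111.1, -111.2], [26.0, 26.1, 26.2], [1.5] * 3)
    df.loc[2, "date"] = df["date"].iloc[1] + pd.Timedelta(days=2)
    with pytest.raises(ValueError, match="contiguous"):
        daily_steps(df)


# --- per-track summaries ---------------------------------------------------

def test_uniform_steps_summary():
    lat_step = 24.0 / (2 * math.pi * 6371 / 360)
    lats = 26.0 + lat_step * np.arange(7)
    df = track_frame([-111.0] * 7, lats, [1.9] * 7)
    row = per_track_summary(daily_steps(df), ptt="x")
    assert row["dist_mean"] == pytest.approx(24.0, rel=1e-9)
    assert row["dist_sd"] == pytest.approx(0.0, abs=1e-9)
    assert row["dist_total"] == pytest.approx(24.0 * 6, rel=1e-9)
    assert row["speed_mean"] == pytest.approx(1.0, rel=1e-9)
    assert np.isnan(row["speed_transiting"])  # no transiting steps -> missing
    assert row["speed_ars"] == pytest.approx(1.0, rel=1e-9)


def test_summary_matches_brute_force():
    rng = np.random.default_rng(2)
    steps = daily_steps(track_frame(
        rng.uniform(-113, -110, 25), rng.uniform(24, 31, 25), rng.uniform(1, 2, 25)
    ))
    row = per_track_summary(steps)
    d = steps["distance_km"].to_numpy()
    assert row["dist_mean"] == pytest.approx(d.mean())
    assert row["dist_sd"] == pytest.approx(d.std(ddof=1))
    assert row["dist_min"] == pytest.approx(d.min())
    assert row["dist_max"] == pytest.approx(d.max())
    assert row["dist_total"] == pytest.approx(d.sum())
    for label, col in [(TRANSITING, "speed_transiting"), (ARS, "speed_ars"),
                       (UNCERTAIN, "speed_uncertain")]:
        sub = steps.loc[steps["label"] == label, "speed_kmh"]
        if len(sub):
            assert row[col] == pytest.approx(sub.mean())
        else:
            assert np.isnan(row[col])


# --- cohort aggregation ----------------------------------------------------

def test_single_row_aggregates_to_itself():
    rows = goc2001_track_summaries().iloc[[2]]
    agg = aggregate_tracks(rows)
    pd.testing.assert_series_equal(agg, rows.iloc[0], check_names=False)


def test_masked_mean_oracle_with_planted_missing():
    rng = np.random.default_rng(3)
    rows = pd.DataFrame(rng.uniform(0, 10, size=(6, 4)),
                        columns=["a", "b", "c", "speed_transiting"])
    rows.loc[[1, 4], "speed_transiting"] = np.nan
    agg = aggregate_tracks(rows)
    for col in rows.columns:
        vals = rows[col].dropna().to_numpy()
        assert agg[col] == pytest.approx(vals.mean())


def test_published_cohort_mean_row():
    agg = aggregate_tracks(goc2001_track_summaries())
    assert round(agg["dist_mean"], 1) == 25.4
    assert round(agg["dist_max"], 2) == 114.16
    assert round(agg["dist_total"], 2) == 7522.46
    assert round(agg["speed_mean"], 2) == 1.06
    assert round(agg["speed_transiting"], 2) == 3.38
    assert round(agg["speed_ars"], 2) == 0.84
    assert round(agg["speed_uncertain"], 2) == 0.53


def test_published_mean_locations_per_day():
    t1 = goc2001_tracking_summary()
    assert round(t1["locs_per_day"].mean(), 1) == 1.7


# --- seasonal proportions --------------------------------------------------

def test_all_ars_everywhere():
    df = pd.DataFrame({"label": [ARS] * 8,
                       "season": ["cool"] * 5 + ["warm"] * 3})
    out = seasonal_mode_proportions(df)
    ars = out[out["label"] == ARS]
    assert (ars["fraction"] == 1.0).all()
    assert set(out["season"]) == {"cool", "warm"}


def test_constructed_fraction_counts():
    df = pd.DataFrame({
        "label": [ARS] * 6 + [TRANSITING] + [UNCERTAIN] * 3,
        "season": ["cool"] * 10,
    })
    out = seasonal_mode_proportions(df).set_index("label")
    assert out.loc[ARS, "fraction"] == 0.6
    assert out.loc[TRANSITING, "fraction"] == 0.1
    assert out.loc[UNCERTAIN, "fraction"] == 0.3


def test_random_labels_match_tally_oracle_and_sum_to_one():
    rng = np.random.default_rng(4)
    labels = rng.choice([ARS, TRANSITING, UNCERTAIN], 200)
    seasons = rng.choice(["cool", "warm"], 200)
    df = pd.DataFrame({"label": labels, "season": seasons})
    out = seasonal_mode_proportions(df)
    for season in ("cool", "warm"):
        sub = out[out["season"] == season]
        assert sub["count"].sum() == (seasons == season).sum()
        assert sub["fraction"].sum() == pytest.approx(1.0)
        for label in (ARS, TRANSITING, UNCERTAIN):
            n = int(((labels == label) & (seasons == season)).sum())
            assert int(sub.set_index("label").loc[label, "count"]) == n


def test_classify_track_locations_labels_every_day():
    df = track_frame([-111.0, -111.1, -111.2], [26.0, 26.1, 26.2],
                     [1.1, 1.5, 1.9], start="2001-11-29")
    out = classify_track_locations(df)
    assert list(out["label"]) == [TRANSITING, UNCERTAIN, ARS]
    assert list(out["season"]) == ["warm", "warm", "cool"]
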