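"""Locality vetting, species climate summaries, and the aridity indices."""

import math

import numpy as np
import pandas as pd
import pytest

import spadefoot as sf
from spadefoot.climate import read_localities


def _records(rows):
    return pd.DataFrame(rows)


BASE = {
    "bio5": 30.0,
    "bio6": -2.0,
    "bio10": 24.0,
    "bio11": 3.0,
    "bio12": 400.0,
    "bio15": 40.0,
    "bio16": 180.0,
}


def _rec(species, lon, lat, elevation=500.0, in_range=True, **kw):
    r = {"species": species, "lon": lon, "lat": lat, "elevation": elevation,
         "in_range": in_range, **BASE}
    r.update(kw)
    return r


class TestVetting:
    def test_exact_duplicates_collapse(self):
        recs = _records(
            [
                _rec("sp1", -100.0, 35.0),
                _rec("sp1", -100.0, 35.0),
                _rec("sp1", -101.0, 35.0),
                _rec("sp1", -100.0, 36.0),
                _rec("sp1", -100.00001, 35.00001),  # same after 4-dp rounding
            ]
        )
        kept, log = sf.vet_localities(recs, 0, 1000)
        assert len(kept) == 3
        assert (log["reason"] == "duplicate_coordinate").sum() == 2

    def test_elevation_interval_filter(self):
        recs = _records(
            [
                _rec("sp1", -100.0, 35.0, elevation=-5.0),
                _rec("sp1", -101.0, 35.0, elevation=500.0),
                _rec("sp1", -102.0, 35.0, elevation=1500.0),
            ]
        )
        kept, log = sf.vet_localities(recs, 0, 1000)
        assert list(kept["elevation"]) == [500.0]
        assert (log["reason"] == "elevation_out_of_bounds").sum() == 2

    def test_range_flag_drops_records(self):
        recs = _records(
            [
                _rec("sp1", -100.0, 35.0, in_range=False),
                _rec("sp1", -101.0, 35.0, in_range=True),
            ]
        )
        kept, log = sf.vet_localities(recs, 0, 1000)
        assert len(kept) == 1
        assert (log["reason"] == "outside_range_map").sum() == 1

    def test_missing_elevation_skips_filter_with_note(self):
        recs = _records(
            [_rec("sp1", -100.0, 35.0, elevation=np.nan), _rec("sp1", -101.0, 35.0)]
        )
        kept, log = sf.vet_localities(recs, 0, 1000)
        assert len(kept) == 2
        assert (log["reason"] == "note_no_elevation").sum() == 1

    def test_matches_brute_force_row_scan(self):
        """Planted violations: the kept set equals an independent row scan."""
        rng = np.random.default_rng(1)
        rows = []
        for i in range(200):
            rows.append(
                _rec(
                    f"sp{i % 4}",
                    float(rng.uniform(-110, -100)),
                    float(rng.uniform(30, 40)),
                    elevation=float(rng.uniform(-100, 3500)),
                    in_range=bool(rng.random() > 0.1),
                )
            )
        recs = _records(rows)
        kept, _ = sf.vet_localities(recs, 0, 3000)
        seen, expect = set(), []
        for i, r in recs.iterrows():
            key = (r["species"], round(r["lon"], 4), round(r["lat"], 4))
            if key in seen:
                continue
            seen.add(key)
            if r["in_range"] and 0 <= r["elevation"] <= 3000:
                expect.append(i)
        assert len(kept) == len(expect)

    def test_idempotent(self):
        recs = _records(
            [_rec("sp1", -100.0, 35.0), _rec("sp1", -100.0, 35.0), _rec("sp1", -99.0, 34.0)]
        )
        kept, _ = sf.vet_localities(recs, 0, 1000)
        again, log2 = sf.vet_localities(kept, 0, 1000)
        pd.testing.assert_frame_equal(kept, again)
        assert not (log2["reason"] != "note_no_elevation").any()

    def test_species_emptied_is_an_error(self):
        recs = _records([_rec("sp1", -100.0, 35.0, in_range=False), _rec("sp2", -99.0, 34.0)])
        with pytest.raises(ValueError, match="sp1"):
            sf.vet_localities(recs, 0, 1000)


class TestSummaries:
    def test_single_locality_collapses(self):
        out = sf.summarize_species(_records([_rec("sp1", -100.0, 35.0, bio12=321.0)]))
        row = out.iloc[0]
        assert row["n_localities"] == 1
        for stat in ("min", "max", "mean", "midpoint"):
            assert row[f"bio12_{stat}"] == 321.0

    def test_minmax_mean_midpoint(self):
        out = sf.summarize_species(
            _records(
                [_rec("sp1", -100.0, 35.0, bio12=100.0), _rec("sp1", -101.0, 35.0, bio12=300.0)]
            )
        )
        row = out.iloc[0]
        assert (row["bio12_min"], row["bio12_max"]) == (100.0, 300.0)
        assert row["bio12_mean"] == 200.0
        assert row["bio12_midpoint"] == 200.0

    def test_streaming_second_pass_oracle(self):
        """1000-record species matches an independent streaming recompute."""
        rng = np.random.default_rng(2)
        rows = [
            _rec("big", float(-100 - i * 1e-3), 35.0, bio12=float(rng.uniform(50, 900)))
            for i in range(1000)
        ]
        out = sf.summarize_species(_records(rows)).iloc[0]
        lo, hi, total, count = math.inf, -math.inf, 0.0, 0
        for r in rows:
            v = r["bio12"]
            lo, hi, total, count = min(lo, v), max(hi, v), total + v, count + 1
        assert out["bio12_min"] == lo and out["bio12_max"] == hi
        assert out["bio12_mean"] == pytest.approx(total / count)
        assert out["bio12_midpoint"] == pytest.approx((lo + hi) / 2)

    def test_permutation_invariant(self):
        rows = [
            _rec("sp1", -100.0 - i, 35.0, bio12=100.0 * (i + 1)) for i in range(5)
        ]
        a = sf.summarize_species(_records(rows))
        b = sf.summarize_species(_records(rows[::-1]).reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b)

    def test_all_missing_variable_flagged_missing(self):
        rows = [_rec("sp1", -100.0, 35.0, bio15=np.nan), _rec("sp1", -101.0, 35.0, bio15=np.nan)]
        out = sf.summarize_species(_records(rows)).iloc[0]
        assert np.isnan(out["bio15_mean"]) and np.isnan(out["bio15_midpoint"])


class TestAridity:
    def test_worked_example(self):
        logq = sf.aridity_logQ(250.0, 38.0, 2.0)
        assert logq == pytest.approx(math.log10(250.0 / (40.0 * 36.0)), abs=1e-12)
        assert logq == pytest.approx(-0.7604, abs=1e-4)

    def test_doubling_precipitation_adds_log2(self):
        a = sf.aridity_logQ(250.0, 38.0, 2.0)
        b = sf.aridity_logQ(500.0, 38.0, 2.0)
        assert b - a == pytest.approx(math.log10(2.0), abs=1e-12)

    def test_monotone_decreasing_in_tmax(self):
        grid = np.linspace(20.0, 45.0, 60)
        vals = [sf.aridity_logQ(400.0, t, 1.0) for t in grid]
        assert np.all(np.diff(vals) < 0)

    def test_logq2_same_formula(self):
        assert sf.aridity_logQ2(250.0, 38.0, 2.0) == sf.aridity_logQ(250.0, 38.0, 2.0)
        assert sf.aridity_logQ2(500.0, 25.0, 5.0) == pytest.approx(-0.0792, abs=1e-4)

    @pytest.mark.parametrize(
        "P,tmax,tmin",
        [(250.0, 2.0, 38.0), (0.0, 38.0, 2.0), (250.0, -2.0, -38.0), (-1.0, 38.0, 2.0)],
    )
    def test_domain_errors(self, P, tmax, tmin):
        with pytest.raises(ValueError):
            sf.aridity_logQ(P, tmax, tmin)

    def test_small_temperature_spread_makes_indices_agree(self):
        """When quarter-mean temperatures track the month extremes and the
        within-species dispersion is small, range-extreme (logQ) and
        locality-mean (logQ2) summarization give nearly identical indices."""
        rng = np.random.default_rng(3)
        rows = []
        for i in range(30):
            t_hot, t_cold = 30.0 + rng.normal(0, 0.2), -2.0 + rng.normal(0, 0.2)
            rows.append(
                _rec(
                    "spA",
                    -100.0 - i * 0.01,
                    35.0,
                    bio5=t_hot,
                    bio6=t_cold,
                    bio10=t_hot + rng.normal(0, 0.2),
                    bio11=t_cold + rng.normal(0, 0.2),
                    bio12=400.0 + rng.normal(0, 5.0),
                )
            )
        out = sf.summarize_species(_records(rows))
        diff = (out["logQ"] - out["logQ2"]).abs()
        assert (diff < 0.1).all()


class TestReader:
    def test_unit_declaration_mandatory(self, tmp_path):
        p = tmp_path / "loc.csv"
        _records([_rec("sp1", -100.0, 35.0)]).to_csv(p, index=False)
        with pytest.raises(ValueError, match="temperature_units"):
            read_localities(p)

    def test_worldclim_raw_scaling(self, tmp_path):
        p = tmp_path / "loc.csv"
        raw = _rec("sp1", -100.0, 35.0, bio5=300.0, bio6=-20.0, bio10=240.0, bio11=30.0)
        _records([raw]).to_csv(p, index=False)
        df = read_localities(p, temperature_units="worldclim-raw")
        assert df.loc[0, "bio5"] == pytest.approx(30.0)
        assert df.loc[0, "bio6"] == pytest.approx(-2.0)
        # precipitation is untouched
        assert df.loc[0, "bio12"] == 400.0
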