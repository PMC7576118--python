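"""Observation I/O, censoring and effort computation."""

import datetime as dt

import pandas as pd
import pytest

from ctds.observations import (
    AvailabilityWindow,
    CameraDeployment,
    MissingWindowError,
    ObservationRecord,
    RowValidationError,
    SchemaError,
    SurveyPeriod,
    build_windows,
    censor_records,
    compute_effort,
    read_observations,
    write_observations,
    read_deployments,
    write_deployments,
)

D = dt.datetime


def _write_csv(path, rows, header="camera_id,timestamp,species,category,distance"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadObservations:
    def test_round_trip_preserves_fields(self, tmp_path):
        rows = [
            "c1,2017-10-02 10:00:00,bighorn_sheep,ewe,5.0",
            "c1,2017-10-02 10:05:00,bighorn_sheep,ram,12.0",
            "c2,2017-10-03 11:00:00,bighorn_sheep,unknown,3.0",
        ]
        f = tmp_path / "obs.csv"
        _write_csv(f, rows)
        records = read_observations(f)
        assert len(records) == 3
        assert [r.category for r in records] == ["ewe", "ram", "unknown"]
        out = tmp_path / "out.csv"
        write_observations(records, out)
        again = read_observations(out)
        assert again == records

    def test_negative_distance_names_the_row(self, tmp_path):
        f = tmp_path / "obs.csv"
        _write_csv(f, [
            "c1,2017-10-02 10:00:00,bighorn_sheep,ewe,5.0",
            "c1,2017-10-02 10:05:00,bighorn_sheep,ram,-1",
        ])
        with pytest.raises(RowValidationError) as exc:
            read_observations(f)
        assert exc.value.failures[0][0] == 1
        assert "negative distance" in exc.value.failures[0][1]

    def test_bad_timestamp_and_category_reported(self, tmp_path):
        f = tmp_path / "obs.csv"
        _write_csv(f, [
            "c1,not-a-time,bighorn_sheep,ewe,5.0",
            "c1,2017-10-02 10:05:00,bighorn_sheep,lamb,2.0",
        ])
        with pytest.raises(RowValidationError) as exc:
            read_observations(f)
        assert {i for i, _ in exc.value.failures} == {0, 1}

    def test_missing_column_is_schema_error(self, tmp_path):
        f = tmp_path / "obs.csv"
        f.write_text("camera_id,timestamp\nc1,2017-10-02\n")
        with pytest.raises(SchemaError):
            read_observations(f)

    def test_xlsx_reader_same_schema(self, tmp_path):
        df = pd.DataFrame(
            {
                "camera_id": ["c1", "c2"],
                "timestamp": ["2017-10-02 10:00:00", "2017-10-03 09:00:00"],
                "species": ["bighorn_sheep"] * 2,
                "category": ["ewe", "ram"],
                "distance": [5.4, 8.0],
            }
        )
        f = tmp_path / "obs.xlsx"
        df.to_excel(f, index=False)
        records = read_observations(f)
        assert [r.distance for r in records] == [5.4, 8.0]

    def test_column_mapping(self, tmp_path):
        f = tmp_path / "obs.csv"
        f.write_text("cam,when,sp,cls,dist_m\nc1,2017-10-02 10:00:00,sheep,ewe,5.0\n")
        recs = read_observations(
            f,
            schema={"camera_id": "cam", "timestamp": "when", "species": "sp",
                    "category": "cls", "distance": "dist_m"},
        )
        assert recs[0].camera_id == "c1" and recs[0].distance == 5.0


def test_deployments_round_trip(tmp_path):
    deps = [
        CameraDeployment(
            "c1", 32.7, -108.7,
            [(D(2017, 10, 1), D(2017, 11, 1)), (D(2017, 12, 1), D(2018, 2, 1))],
        ),
        CameraDeployment("c2", 32.71, -108.69, [(D(2017, 10, 1), D(2018, 2, 1))]),
    ]
    f = tmp_path / "dep.csv"
    write_deployments(deps, f)
    again = read_deployments(f)
    assert again == deps


def test_overlapping_operational_intervals_rejected():
    with pytest.raises(ValueError, match="overlap"):
        CameraDeployment("c1", 0, 0, [(D(2017, 10, 1), D(2017, 11, 1)),
                                      (D(2017, 10, 20), D(2017, 12, 1))])


class TestCensoring:
    WIN = {
        dt.date(2017, 10, 2): AvailabilityWindow(
            dt.date(2017, 10, 2), D(2017, 10, 2, 5, 30), D(2017, 10, 2, 20, 0)
        )
    }

    @staticmethod
    def _rec(ts):
        return ObservationRecord("c1", ts, "bighorn_sheep", "ewe", 5.0)

    def test_window_membership(self):
        noon = self._rec(D(2017, 10, 2, 12, 0))
        night = self._rec(D(2017, 10, 2, 23, 59))
        kept, frac = censor_records([noon, night], self.WIN)
        assert kept == [noon]
        assert frac == 0.5

    def test_all_inside_gives_zero_fraction(self):
        recs = [self._rec(D(2017, 10, 2, h, 0)) for h in (6, 10, 14, 18)]
        kept, frac = censor_records(recs, self.WIN)
        assert kept == recs and frac == 0.0

    def test_missing_window_raises(self):
        with pytest.raises(MissingWindowError):
            censor_records([self._rec(D(2017, 10, 3, 12, 0))], self.WIN)


class TestEffort:
    PERIOD = SurveyPeriod("p", dt.date(2017, 10, 2), dt.date(2017, 10, 2))
    WIN = TestCensoring.WIN

    def _dep(self, start, end, t=15.0, theta=50.0):
        return CameraDeployment("c1", 32.7, -108.7, [(start, end)],
                                trigger_interval_t=t, fov_theta=theta)

    def test_effort_arithmetic(self):
        dep = self._dep(D(2017, 10, 2, 10, 0), D(2017, 10, 2, 11, 0))
        eff = compute_effort([dep], self.WIN, self.PERIOD)
        row = eff.table.iloc[0]
        assert row["available_seconds"] == 3600.0
        assert row["snapshots"] == 240.0
        assert row["effective_effort"] == pytest.approx(240 * 50 / 360)

    def test_full_circle_theta_identity(self):
        dep = self._dep(D(2017, 10, 2, 10, 0), D(2017, 10, 2, 11, 0), theta=360.0)
        eff = compute_effort([dep], self.WIN, self.PERIOD)
        row = eff.table.iloc[0]
        assert row["effective_effort"] == row["snapshots"]

    def test_doubling_t_halves_snapshots(self):
        dep15 = self._dep(D(2017, 10, 2, 10, 0), D(2017, 10, 2, 11, 0), t=15)
        dep30 = self._dep(D(2017, 10, 2, 10, 0), D(2017, 10, 2, 11, 0), t=30)
        s15 = compute_effort([dep15], self.WIN, self.PERIOD).table.iloc[0]["snapshots"]
        s30 = compute_effort([dep30], self.WIN, self.PERIOD).table.iloc[0]["snapshots"]
        assert s15 == 2 * s30

    def test_operational_clipped_to_window(self):
        # operating all night contributes nothing outside the diel window
        dep = self._dep(D(2017, 10, 1, 0, 0), D(2017, 10, 3, 0, 0))
        eff = compute_effort([dep], self.WIN, self.PERIOD)
        assert eff.table.iloc[0]["available_seconds"] == pytest.approx(14.5 * 3600)

    def test_zero_effort_warns_not_fails(self):
        dep = self._dep(D(2017, 10, 2, 22, 0), D(2017, 10, 2, 23, 0))
        with pytest.warns(UserWarning, match="zero effort"):
            eff = compute_effort([dep], self.WIN, self.PERIOD)
        assert eff.total_snapshots == 0.0

    def test_available_seconds_bounded_by_period_length(self):
        period = SurveyPeriod("p", dt.date(2018, 3, 1), dt.date(2018, 3, 10))
        windows = build_windows(period, 32.7, -108.7, -7.0)
        dep = self._dep(D(2018, 2, 1), D(2018, 4, 1))
        eff = compute_effort([dep], windows, period)
        assert eff.table.iloc[0]["available_seconds"] <= 10 * 86400
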