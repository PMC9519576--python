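"""Monitor-file parsing, metadata validation and series assembly."""

from datetime import datetime, time, timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitosleep import dam_io
from mitosleep.dam_io import (
    ChannelMeta,
    DamFormatError,
    MonitorRecord,
    assemble_series,
    read_channel_meta,
    read_monitor_file,
    schedule_light,
    write_channel_meta,
    write_monitor_file,
)


def _record(i, ts, counts):
    return MonitorRecord(
        index=i, timestamp=ts, status=1,
        extras=("0", "0", "0", "0", "0", "1"),
        counts=np.asarray(counts, dtype=np.int64),
    )


def _meta(channel=1, status="fly", line="ORT", **kw):
    base = dict(
        monitor_id="M1", channel=channel, line=line, sex="female",
        genome_type="coevolved", haplogroup="I", block="B1", replicate=1,
        status=status,
    )
    base.update(kw)
    return ChannelMeta(**base)


class TestMonitorFile:
    def test_three_row_fixture_parses_fieldwise(self, tmp_path):
        """Counts land in the right channels and timestamps parse."""
        t0 = datetime(2021, 9, 20, 9, 0)
        rows = [np.zeros(32, int), np.zeros(32, int), np.zeros(32, int)]
        rows[1][0] = 1
        recs = [_record(i + 1, t0 + timedelta(minutes=i), c) for i, c in enumerate(rows)]
        path = tmp_path / "m.txt"
        write_monitor_file(recs, path)
        parsed = read_monitor_file(path)
        assert len(parsed) == 3
        assert [r.counts[0] for r in parsed] == [0, 1, 0]
        assert parsed[0].timestamp == t0
        assert all(r.valid for r in parsed)

    def test_write_read_round_trip_is_byte_exact(self, tmp_path, small_experiment):
        scenario, records, *_ = small_experiment
        for monitor_id, recs in records.items():
            p1 = tmp_path / f"{monitor_id}.txt"
            write_monitor_file(recs, p1)
            p2 = tmp_path / f"{monitor_id}_again.txt"
            write_monitor_file(read_monitor_file(p1), p2)
            assert p1.read_bytes() == p2.read_bytes()

    def test_three_day_file_has_4320_records(self, tmp_path):
        from mitosleep.synthetic_data import SimScenario, simulate_experiment

        sc = SimScenario(n_lines_per_panel=2, n_per_sex_line=1, n_blocks=1, days=3)
        records, _, _ = simulate_experiment(sc, out_dir=tmp_path, seed=0)
        for recs in records.values():
            assert len(recs) == 3 * 24 * 60

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda lines: lines[1].rsplit("\t", 1)[0],  # 41 fields
            lambda lines: lines[1].replace("\t0", "\tx", 1),  # non-integer count
        ],
    )
    def test_malformed_row_names_line_number(self, tmp_path, mutate):
        t0 = datetime(2021, 9, 20, 9, 0)
        recs = [_record(i + 1, t0 + timedelta(minutes=i), np.zeros(32, int)) for i in range(3)]
        path = tmp_path / "m.txt"
        write_monitor_file(recs, path)
        lines = path.read_text().splitlines()
        lines[1] = mutate(lines)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(DamFormatError, match=":2:"):
            read_monitor_file(path)

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        t0 = datetime(2021, 9, 20, 9, 0)
        recs = [
            _record(1, t0, np.zeros(32, int)),
            _record(2, t0 - timedelta(minutes=1), np.zeros(32, int)),
        ]
        path = tmp_path / "m.txt"
        write_monitor_file(recs, path)
        with pytest.raises(DamFormatError, match="increase"):
            read_monitor_file(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        with pytest.raises(DamFormatError, match="empty"):
            read_monitor_file(path)

    @given(
        counts=st.lists(
            st.lists(st.integers(0, 99), min_size=32, max_size=32),
            min_size=1,
            max_size=8,
        )
    )
    def test_round_trip_preserves_counts(self, counts):
        import tempfile
        from pathlib import Path

        t0 = datetime(2021, 9, 20, 9, 0)
        recs = [_record(i + 1, t0 + timedelta(minutes=i), c) for i, c in enumerate(counts)]
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "h.txt"
            write_monitor_file(recs, path)
            back = read_monitor_file(path)
        assert all(
            np.array_equal(a.counts, b.counts) and a.timestamp == b.timestamp
            for a, b in zip(recs, back)
        )


class TestChannelMeta:
    def test_haplogroup_autofilled_from_line(self, tmp_path):
        path = tmp_path / "meta.csv"
        path.write_text(
            "monitor_id,channel,line,sex,genome_type,haplogroup,block,replicate,status\n"
            "M1,5,KSA2,female,cybrid,,B1,2,fly\n"
            "M1,6,PYR2,male,coevolved,,B1,1,fly\n"
        )
        meta = read_channel_meta(path)
        assert meta[0].haplogroup == "I"
        assert meta[1].haplogroup == "II"

    def test_duplicate_channel_rejected(self, tmp_path):
        path = tmp_path / "meta.csv"
        path.write_text(
            "monitor_id,channel,line,sex,genome_type,haplogroup,block,replicate,status\n"
            "M1,5,KSA2,female,cybrid,I,B1,2,fly\n"
            "M1,5,ORT,male,coevolved,I,B1,1,fly\n"
        )
        with pytest.raises(DamFormatError, match="duplicate"):
            read_channel_meta(path)

    def test_unknown_line_without_haplogroup_rejected(self, tmp_path):
        path = tmp_path / "meta.csv"
        path.write_text(
            "monitor_id,channel,line,sex,genome_type,haplogroup,block,replicate,status\n"
            "M1,5,NOPE,female,cybrid,,B1,2,fly\n"
        )
        with pytest.raises(DamFormatError, match="unknown line"):
            read_channel_meta(path)

    def test_inconsistent_haplogroup_rejected(self, tmp_path):
        path = tmp_path / "meta.csv"
        path.write_text(
            "monitor_id,channel,line,sex,genome_type,haplogroup,block,replicate,status\n"
            "M1,5,KSA2,female,cybrid,II,B1,2,fly\n"
        )
        with pytest.raises(DamFormatError, match="inconsistent"):
            read_channel_meta(path)

    def test_round_trip(self, tmp_path, small_experiment):
        _, _, meta, _, _ = small_experiment
        path = tmp_path / "meta.csv"
        write_channel_meta(meta, path)
        assert read_channel_meta(path) == list(meta)


class TestAssembly:
    def _records(self, days=3):
        t0 = datetime(2021, 9, 20, 9, 0)
        rng = np.random.default_rng(0)
        return [
            _record(i + 1, t0 + timedelta(minutes=i), rng.poisson(0.5, 32))
            for i in range(days * 1440)
        ]

    def test_twelve_twelve_light_symmetry(self):
        recs = self._records()
        series = assemble_series(recs, [_meta()], lights_on=time(9, 0))
        (s,) = series
        assert int(s.light.sum()) == 2160
        assert len(s.light) - int(s.light.sum()) == 2160

    def test_empty_channel_emits_no_series(self):
        recs = self._records(days=3)
        meta = [_meta(channel=1), _meta(channel=2, status="empty", line="", sex="",
                                        genome_type="", haplogroup="")]
        series = assemble_series(recs, meta)
        assert [s.meta.channel for s in series] == [1]

    def test_channel_out_of_range_rejected(self):
        with pytest.raises(DamFormatError, match="outside"):
            assemble_series(self._records(), [_meta(channel=33)])

    def test_series_counts_match_source_column(self):
        recs = self._records()
        (s,) = assemble_series(recs, [_meta(channel=7)])
        col = np.array([r.counts[6] for r in recs])
        assert int(s.counts.sum()) == int(col.sum())

    def test_no_complete_window_rejected(self):
        recs = self._records(days=1)
        with pytest.raises(DamFormatError, match="window"):
            assemble_series(recs, [_meta()], window_days=3)

    def test_light_fraction_matches_photoperiod(self):
        recs = self._records()
        (s,) = assemble_series(recs, [_meta()], photoperiod_h=8.0)
        assert s.light.mean() == pytest.approx(8 / 24)

    def test_schedule_light_wraps_midnight(self):
        ts = np.array(
            [datetime(2021, 9, 20, 20, 59), datetime(2021, 9, 20, 21, 0)],
            dtype="datetime64[s]",
        )
        light = schedule_light(ts, lights_on=time(9, 0))
        assert light.tolist() == [1, 0]
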