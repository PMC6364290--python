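import numpy as np
import pandas as pd
import pytest

from ifresp import DataError, build_info, convert_aquaresp, import_meas, import_test
from ifresp.logger_io import get_dialect, read_generic, read_set, write_generic, write_set


def _generic_lines(rows):
    header = "Date.Time\tPhase\tTemp\t" + "\t".join(
        f"Ox.{i + 1}" for i in range(len(rows[0]) - 3)
    )
    return "\n".join([header] + ["\t".join(str(v) for v in r) for r in rows]) + "\n"


def _write_phases(path, phase_specs, n_chamber=1, dt_s=60):
    """phase_specs: list of (label, start 'dd/mm/yyyy HH:MM:SS', n_points)."""
    rows = []
    for label, start, n in phase_specs:
        t0 = pd.Timestamp(pd.to_datetime(start, format="%d/%m/%Y %H:%M:%S"))
        for k in range(n):
            ts = (t0 + pd.Timedelta(seconds=k * dt_s)).strftime("%d/%m/%Y %H:%M:%S")
            rows.append([ts, label, 16.5, *[round(9.5 - 0.001 * k, 4)] * n_chamber])
    path.write_text(_generic_lines(rows), encoding="utf-8")
    return path


class TestImportTest:
    def test_blank_import_keeps_measurement_phase(self, info4, exp_files):
        pre = import_test(exp_files["pre"], info4)
        assert pre.kind == "background_test"
        spans = pre.measurement_phases
        assert len(spans) == 1
        assert spans[0].n_points == 600
        for ch in info4.chamber_ids:
            assert pre.data[ch].notna().sum() == 600

    def test_chamber_count_mismatch(self, tmp_path, info4):
        path = _write_phases(tmp_path / "t.txt", [("M1", "01/06/2020 10:00:00", 5)], n_chamber=3)
        with pytest.raises(DataError, match="columns"):
            import_test(path, info4)  # metadata describes 4 chambers

    def test_empty_file(self, tmp_path, info4):
        path = tmp_path / "empty.txt"
        path.write_text("", encoding="utf-8")
        with pytest.raises(DataError):
            import_test(path, info4)

    def test_unparseable_line_reports_line_number(self, tmp_path):
        info = build_info(["A"], [1.0], [100.0], "mg/L")
        path = tmp_path / "bad.txt"
        path.write_text(
            "Date.Time\tPhase\tTemp\tOx.1\n"
            "01/06/2020 10:00:00\tM1\t16.5\t9.5\n"
            "01/06/2020 10:00:01\tM1\tnot_a_number\t9.4\n",
            encoding="utf-8",
        )
        with pytest.raises(DataError, match="line 3"):
            import_test(path, info)


class TestImportMeasWindow:
    def _file(self, tmp_path):
        info = build_info(["A"], [1.0], [100.0], "mg/L")
        # phases: 21:50–22:10, 22:30–22:50, 05:40–06:00 (next day)
        path = _write_phases(
            tmp_path / "m.txt",
            [
                ("M1", "01/06/2020 21:50:00", 21),
                ("M2", "01/06/2020 22:30:00", 21),
                ("M3", "02/06/2020 05:40:00", 21),
            ],
        )
        return path, info

    def test_midnight_aware_containment(self, tmp_path):
        path, info = self._file(tmp_path)
        ms = import_meas(path, info, start_measure="22:00:00", stop_measure="06:00:00")
        # the 21:50 phase starts before the window opens; the other two are inside
        assert [p.label for p in ms.measurement_phases] == ["M1", "M2"]
        assert len(ms.measurement_phases) == 2

    def test_degenerate_window_means_full_day(self, tmp_path):
        path, info = self._file(tmp_path)
        ms = import_meas(path, info, start_measure="00:00:00", stop_measure="00:00:00")
        assert len(ms.measurement_phases) == 3

    def test_widening_never_drops_phases(self, tmp_path):
        path, info = self._file(tmp_path)
        narrow = import_meas(path, info, start_measure="22:00:00", stop_measure="06:00:00")
        wide = import_meas(path, info, start_measure="21:00:00", stop_measure="07:00:00")
        assert len(wide.measurement_phases) >= len(narrow.measurement_phases)

    def test_no_surviving_phase_is_an_error(self, tmp_path):
        path, info = self._file(tmp_path)
        with pytest.raises(DataError, match="none of the 3"):
            import_meas(path, info, start_measure="12:00:00", stop_measure="13:00:00")

    def test_phases_reindexed_in_time_order(self, tmp_path):
        path, info = self._file(tmp_path)
        ms = import_meas(path, info)
        assert [p.label for p in ms.measurement_phases] == ["M1", "M2", "M3"]

    def test_overnight_cycle_count(self, info4, tmp_path):
        # 300/180/720 s cycles starting 21:00; window 22:00-06:00 keeps the
        # cycles whose measurement phase lies fully inside the 8 h window
        from ifresp import BackgroundSpec, SimSpec, generate_experiment

        spec = SimSpec(
            chambers=info4.chambers,
            true_mo2=(200.0, 200.0, 200.0, 200.0),
            flush_s=300, wait_s=180, measure_s=720,
            n_cycles=30,
            background=BackgroundSpec("constant", -0.05),
            sample_dt_s=10,
            start_time="01/06/2020 21:00:00",
            seed=3,
        )
        generate_experiment(spec, tmp_path / "m.txt")
        all_phases = import_meas(tmp_path / "m.txt", info4).measurement_phases
        windowed = import_meas(
            tmp_path / "m.txt", info4, start_measure="22:00:00", stop_measure="06:00:00"
        ).measurement_phases
        expected = sum(
            1
            for p in all_phases
            if (p.start.hour >= 22 or p.start.hour < 6)
            and (p.end.hour >= 22 or p.end.hour < 6 or (p.end.hour == 6 and p.end.minute == 0 and p.end.second == 0))
        )
        assert len(windowed) == expected
        assert 0 < len(windowed) < len(all_phases)


class TestGenericRoundTrip:
    def test_write_read_lossless(self, tmp_path):
        df = pd.DataFrame(
            {
                "time": pd.date_range("2020-06-01 22:00:00", periods=6, freq="1s"),
                "phase": ["M1"] * 6,
                "temp": [16.512, 16.5, 16.49, 16.51, 16.5, 16.48],
                "Ox.1": np.linspace(9.5, 9.45, 6),
                "Ox.2": np.linspace(9.4, 9.35, 6),
            }
        )
        path = write_generic(df, ["Ox.1", "Ox.2"], tmp_path / "g.txt")
        back, cols = read_generic(path)
        assert cols == ["Ox.1", "Ox.2"]
        assert (back["time"] == df["time"]).all()
        assert (back["phase"] == df["phase"]).all()
        assert np.allclose(back["temp"], df["temp"], atol=5e-4)
        assert np.allclose(back[cols], df[cols], atol=5e-10)

    def test_whitespace_and_decimal_comma_tolerated(self, tmp_path):
        info = build_info(["A"], [1.0], [100.0], "mg/L")
        path = tmp_path / "loose.txt"
        path.write_text(
            "Date.Time Phase Temp Ox.1\n"
            "01/06/2020 10:00:00 M1 16,5 9,43\n"
            "01/06/2020 10:00:01 M1 16,5 9,42\n",
            encoding="utf-8",
        )
        ms = import_test(path, info)
        assert ms.data["CH1"].iloc[0] == pytest.approx(9.43)

    def test_measurement_set_round_trip(self, info4, exp_files):
        ms = import_meas(exp_files["meas"], info4)
        path = exp_files["dir"] / "persisted.txt"
        write_set(ms, path)
        back = read_set(path, info4)
        assert back.kind == ms.kind
        assert len(back.data) == len(ms.data)
        assert np.allclose(back.data["CH1"], ms.data["CH1"], atol=1e-8)


class TestAutoRespDialect:
    def test_multichannel_pair_layout(self, tmp_path):
        info = build_info(["A", "B"], [1.0, 1.1], [100.0, 100.0], "mg/L")
        lines = ["junk header"] * 38
        for k in range(4):
            ts = f"01/06/2020 10:00:{k:02d}"
            lines.append(f"{ts}\tM1\t0.0\t16.5\t{9.5 - 0.01 * k}\t16.6\t{9.4 - 0.01 * k}")
        path = tmp_path / "ar.txt"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        ms = import_test(path, info, logger="autoresp")
        assert ms.data["CH1"].iloc[0] == pytest.approx(9.5)
        assert ms.data["CH2"].iloc[0] == pytest.approx(9.4)
        assert ms.data["temp"].iloc[0] == pytest.approx(16.55)  # mean of per-chamber temps


class TestAquaRespConversion:
    def _summary(self, tmp_path, measure=720):
        path = tmp_path / "summary.txt"
        path.write_text(
            "ExperimentStart: 01/06/2020 22:00:00\n"
            "FlushTime: 300\nWaitTime: 180\n"
            f"MeasureTime: {measure}\nCycles: 2\n",
            encoding="utf-8",
        )
        return path

    def _presens(self, tmp_path, n=2400, dt=1):
        rows = ["Date;Time;Logtime/s;Oxygen;Temp"]
        t0 = pd.Timestamp("2020-06-01 22:00:00")
        for k in range(0, n, dt):
            ts = t0 + pd.Timedelta(seconds=k)
            rows.append(
                ts.strftime("%d/%m/%Y;%H:%M:%S") + f";{k};{9.5 - 0.0001 * k:.4f};16,5"
            )
        path = tmp_path / "oxy.txt"
        path.write_text("\n".join(rows) + "\n", encoding="utf-8")
        return path

    def test_presens_round_trip(self, tmp_path):
        logger = self._presens(tmp_path)
        out = convert_aquaresp(logger, self._summary(tmp_path), tmp_path / "gen.txt", "presens")
        info = build_info(["A"], [1.0], [100.0], "mg/L")
        ms = import_meas(out, info)
        spans = ms.measurement_phases
        assert len(spans) == 2
        for span in spans:
            assert 710 <= span.duration_s <= 720

    def test_zero_measure_duration_rejected(self, tmp_path):
        with pytest.raises(DataError, match="non-positive measurement"):
            convert_aquaresp(
                self._presens(tmp_path, n=100),
                self._summary(tmp_path, measure=0),
                tmp_path / "out.txt",
                "presens",
            )

    def test_flavour_mismatch_is_parse_error(self, tmp_path):
        logger = self._presens(tmp_path, n=100)
        with pytest.raises(DataError, match="flavour"):
            convert_aquaresp(logger, self._summary(tmp_path), tmp_path / "o.txt", "pyroscience")

    def test_timestamps_before_start_rejected(self, tmp_path):
        path = tmp_path / "early.txt"
        path.write_text(
            "Date;Time;Logtime/s;Oxygen;Temp\n"
            "01/06/2020;21:00:00;0;9.5;16.5\n",
            encoding="utf-8",
        )
        with pytest.raises(DataError, match="precedes"):
            convert_aquaresp(path, self._summary(tmp_path), tmp_path / "o.txt", "presens")


class TestDialects:
    def test_unknown_dialect(self):
        with pytest.raises(DataError, match="unknown logger dialect"):
            get_dialect("excel", 4)

    def test_aquaresp_dialects_point_to_converter(self):
        with pytest.raises(DataError, match="convert_aquaresp"):
            get_dialect("aquaresp_presens", 1)

    def test_qbox_is_single_chamber(self):
        with pytest.raises(DataError, match="single-chamber"):
            get_dialect("qboxaqua", 2)


class TestExportResults:
    def _mr(self, info, slopes, trait):
        import pandas as pd

        from ifresp import calculate_mr
        from ifresp.slopes import SlopeRecord, SlopeTable

        records = []
        for ch, s in zip(info.chamber_ids, slopes):
            records.append(SlopeRecord(
                chamber_id=ch, phase_label="M1", slope=s, r2=1.0, window_s=600.0,
                n_points=600, phase_midtime=pd.Timestamp("2020-06-01 23:00:00"),
                background_b=0.0, raw_slope=s,
            ))
        table = SlopeTable(info=info, records=records, selected=records,
                           selection_method="all", r2_threshold=0.95)
        return calculate_mr(table, info, trait=trait)

    def test_simplified_export_is_one_row_per_fish(self, tmp_path):
        from ifresp import export_results

        info = build_info(["F1", "F2"], [1.0, 1.2], [100.0, 100.0], "mg/L")
        smr = self._mr(info, [-1.0, -1.2], "SMR")
        out = export_results(smr, path=tmp_path / "r.csv", simplify=True)
        assert len(out) == 2
        assert set(out["ID"]) == {"F1", "F2"}
        assert (tmp_path / "r.csv").exists()

    def test_scope_columns_present_with_ms(self, tmp_path):
        from ifresp import export_results

        info = build_info(["F1"], [1.0], [100.0], "mg/L")
        smr = self._mr(info, [-1.0], "SMR")
        amr = self._mr(info, [-3.0], "AMR")
        out = export_results(smr, amr, path=tmp_path / "r.txt", simplify=True, ms=True)
        assert out["Scope.factorial"].iloc[0] == pytest.approx(3.0)
        assert out["Scope.mass"].iloc[0] == pytest.approx(
            out["AMR.mass"].iloc[0] - out["SMR.mass"].iloc[0]
        )
        # .txt extension writes tab-separated
        assert "\t" in (tmp_path / "r.txt").read_text().splitlines()[0]

    def test_missing_fish_error_names_the_id(self):
        from ifresp import export_results

        info2 = build_info(["F1", "F2"], [1.0, 1.2], [100.0, 100.0], "mg/L")
        info1 = build_info(["F1"], [1.0], [100.0], "mg/L")
        smr = self._mr(info2, [-1.0, -1.2], "SMR")
        amr = self._mr(info1, [-3.0], "AMR")
        with pytest.raises(DataError, match="F2"):
            export_results(smr, amr, simplify=True, ms=True)

    def test_long_format_has_one_row_per_phase(self):
        from ifresp import export_results

        info = build_info(["F1", "F2"], [1.0, 1.2], [100.0, 100.0], "mg/L")
        smr = self._mr(info, [-1.0, -1.2], "SMR")
        out = export_results(smr, simplify=False)
        assert len(out) == len(smr.records)
        assert (out["Trait"] == "SMR").all()
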