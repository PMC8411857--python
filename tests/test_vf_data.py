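import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vfarch import grid, vf_data
from vfarch.errors import ValidationError
from vfarch.vf_data import EyeSeries, VisualField, surrogate_md, surrogate_psd


def _field(eye="e1", visit="baseline", td=None, md=None, fl=0.1, fp=0.05, lat="OD"):
    td = np.zeros(54) if td is None else np.asarray(td, dtype=float)
    return VisualField(
        eye_id=eye,
        laterality=lat,
        visit=visit,
        td=td,
        md=surrogate_md(td) if md is None else md,
        psd=surrogate_psd(td),
        fixation_loss_rate=fl,
        false_positive_rate=fp,
    )


class TestReliability:
    def test_reliable_below_both_cutoffs(self):
        assert _field(fl=0.32, fp=0.14).reliable

    @pytest.mark.parametrize("fl,fp", [(0.33, 0.0), (0.40, 0.0), (0.0, 0.15), (0.0, 0.2)])
    def test_unreliable_at_or_above_either_cutoff(self, fl, fp):
        assert not _field(fl=fl, fp=fp).reliable

    def test_filter_reliable_counts(self):
        fields = [_field(visit=v) for v in ("baseline", "m1", "m2", "m3")]
        fields.append(_field(visit="m4", fl=0.5))
        out = vf_data.filter_reliable(EyeSeries(eye_id="e1", fields=fields))
        assert len(out.fields) == 4
        # all reliable -> identity; all unreliable -> empty with warning
        same = vf_data.filter_reliable(EyeSeries(eye_id="e1", fields=fields[:4]))
        assert len(same.fields) == 4
        with pytest.warns(UserWarning):
            empty = vf_data.filter_reliable(
                EyeSeries(eye_id="e1", fields=[_field(fl=0.9)])
            )
        assert empty.fields == []


class TestAverageReplicates:
    def test_single_field_identity(self):
        f = _field()
        assert vf_data.average_replicates([f]) is f

    def test_opposite_fields_average_to_zero(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=54)
        out = vf_data.average_replicates([_field(td=t), _field(td=-t)])
        assert np.allclose(out.td, 0.0)

    def test_pointwise_mean(self):
        a, b = np.full(54, -4.0), np.full(54, -2.0)
        out = vf_data.average_replicates([_field(td=a), _field(td=b)])
        assert np.allclose(out.td, -3.0)
        assert out.md == pytest.approx(-3.0)

    def test_mixed_eye_or_visit_rejected(self):
        with pytest.raises(ValidationError):
            vf_data.average_replicates([_field(eye="a"), _field(eye="b")])
        with pytest.raises(ValidationError):
            vf_data.average_replicates([_field(visit="m1"), _field(visit="m2")])

    @given(st.permutations(list(range(4))))
    def test_permutation_invariant(self, order):
        rng = np.random.default_rng(3)
        fields = [_field(td=rng.normal(size=54)) for _ in range(4)]
        base = vf_data.average_replicates(fields)
        perm = vf_data.average_replicates([fields[i] for i in order])
        # invariant up to float summation order
        assert np.allclose(base.td, perm.td, rtol=0, atol=1e-12)


class TestTreatmentFailure:
    def _series(self, mds, baseline_md):
        fields = [_field(visit="baseline", td=np.full(54, baseline_md))]
        for i, md in enumerate(mds):
            fields.append(_field(visit=f"m{i+1}", td=np.full(54, md)))
        return EyeSeries(eye_id="e1", fields=fields)

    def test_confirmed_two_db_drop_in_worse_stratum(self):
        # baseline -4.0 (<= -3.5 stratum): 2.2 dB drop confirmed next visit
        s = self._series([-6.2, -6.3], baseline_md=-4.0)
        assert vf_data.detect_treatment_failure(s) == (True, "m1")

    def test_unconfirmed_drop_is_not_failure(self):
        # baseline -2.5 (3 dB stratum): -5.0 not confirmed (next is -3.0)
        s = self._series([-5.0, -3.0], baseline_md=-2.5)
        assert vf_data.detect_treatment_failure(s) == (False, None)

    def test_flat_series_no_failure(self):
        s = self._series([-4.1, -3.9, -4.0], baseline_md=-4.0)
        assert vf_data.detect_treatment_failure(s) == (False, None)

    def test_milder_stratum_requires_three_db(self):
        s = self._series([-5.0, -5.1], baseline_md=-2.5)  # 2.5 dB drop only
        assert vf_data.detect_treatment_failure(s) == (False, None)
        s2 = self._series([-5.6, -5.7], baseline_md=-2.5)  # 3.1 dB drop
        assert vf_data.detect_treatment_failure(s2) == (True, "m1")


class TestCurateOutcomeWindow:
    def test_visits_after_month_six_dropped(self):
        fields = [_field(visit=v) for v in ("baseline", "m1", "m6", "m7", "m12")]
        out = vf_data.curate_outcome_window(EyeSeries(eye_id="e1", fields=fields))
        assert out.visits() == ["baseline", "m1", "m6"]

    def test_treatment_failure_field_carried_forward(self):
        td_fail = np.full(54, -8.0)
        fields = [_field(visit="baseline")]
        fields += [_field(visit=f"m{i}") for i in (1, 2)]
        fields.append(_field(visit="m3", td=td_fail))
        fields += [_field(visit=f"m{i}", td=np.full(54, -1.0)) for i in (4, 5, 6)]
        s = EyeSeries(
            eye_id="e1", fields=fields,
            failure_status="treatment_failure", failure_visit="m3",
        )
        out = vf_data.curate_outcome_window(s)
        for v in ("m4", "m5", "m6"):
            f = next(f for f in out.fields if f.visit == v)
            assert np.array_equal(f.td, td_fail)

    def test_baseline_replicates_averaged(self):
        fields = [
            _field(visit="baseline", td=np.full(54, -4.0)),
            _field(visit="baseline", td=np.full(54, -2.0)),
            _field(visit="m1"),
        ]
        out = vf_data.curate_outcome_window(EyeSeries(eye_id="e1", fields=fields))
        base = [f for f in out.fields if f.visit == "baseline"]
        assert len(base) == 1
        assert np.allclose(base[0].td, -3.0)

    def test_never_emits_unreliable_and_never_adds_visits(self, small_cohort):
        series, _ = small_cohort
        for s in series:
            out = vf_data.curate_outcome_window(s)
            assert all(f.reliable for f in out.fields)
            assert len(out.visits()) <= len(s.visits())


class TestCohortIO:
    def test_three_row_file_one_eye(self, tmp_path):
        fields = [
            _field(visit="baseline"),
            _field(visit="baseline"),
            _field(visit="m1"),
        ]
        path = tmp_path / "c.csv"
        vf_data.write_cohort([EyeSeries(eye_id="e1", fields=fields)], path)
        back = vf_data.read_cohort(path)
        assert len(back) == 1 and len(back[0].fields) == 3

    def test_unreliable_flag_set_from_rates(self, tmp_path):
        path = tmp_path / "c.csv"
        vf_data.write_cohort(
            [EyeSeries(eye_id="e1", fields=[_field(fl=0.40)])], path
        )
        assert not vf_data.read_cohort(path)[0].fields[0].reliable

    def test_os_mirroring_on_load(self, tmp_path):
        # an OS row with a defect at its within-row position 1 of the y=3 row
        # must land at the mirrored canonical location (-21, 3)
        td = np.zeros(54)
        row_start = 4 + 6 + 8
        td[row_start + 1] = -20.0
        f = _field(td=td, lat="OS")
        path = tmp_path / "c.csv"
        vf_data.write_cohort([EyeSeries(eye_id="e1", fields=[f])], path, mirror_os=False)
        back = vf_data.read_cohort(path, mirror_os=True)
        assert back[0].fields[0].td[grid.index_of(-21, 3)] == -20.0

    def test_round_trip_bit_identical(self, tmp_path, small_cohort):
        series, _ = small_cohort
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        vf_data.write_cohort(series, p1)
        back = vf_data.read_cohort(p1)
        orig_td = np.array([f.td for s in series for f in s.fields])
        back_td = np.array([f.td for s in back for f in s.fields])
        assert np.array_equal(orig_td, back_td)
        vf_data.write_cohort(back, p2)
        assert p1.read_text() == p2.read_text()

    def test_missing_column_and_bad_rows_reported(self, tmp_path):
        path = tmp_path / "c.csv"
        vf_data.write_cohort([EyeSeries(eye_id="e1", fields=[_field()])], path)
        text = path.read_text()
        # missing required column
        broken = tmp_path / "broken.csv"
        broken.write_text(text.replace("td_54", "other"))
        with pytest.raises(ValidationError, match="missing required column"):
            vf_data.read_cohort(broken)
        # non-numeric td entry names the line
        lines = text.splitlines()
        cells = lines[1].split(",")
        cells[-1] = "abc"
        (tmp_path / "row.csv").write_text(lines[0] + "\n" + ",".join(cells) + "\n")
        with pytest.raises(ValidationError, match="line 2"):
            vf_data.read_cohort(tmp_path / "row.csv")


def test_surrogate_indices_ignore_blind_spot():
    td = np.zeros(54)
    td[grid.blind_spot_indices()] = -30.0
    assert surrogate_md(td) == 0.0
    assert surrogate_psd(td) == 0.0
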