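import numpy as np
import pytest

from sexscaff import sex_assignment as sa
from sexscaff.core import CallClass, CovState, RegionClass, Sex
from sexscaff.coverage_model import StateSegmentation
from sexscaff import synthetic_data as sd


def seg(contig, states):
    states = np.array([int(s) for s in states], dtype=np.int8)
    segments = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            segments.append((start, i - 1, CovState(int(states[start]))))
            start = i
    return StateSegmentation(contig, states, 0.0, segments)


Z, H, F, E = CovState.ZERO, CovState.HALF, CovState.FULL, CovState.EXCESS


class TestRuleTable:
    def test_all_sixteen_level_pairs(self):
        expected = {
            (F, F): CallClass.AUTOSOME,
            (H, H): CallClass.HAPLOTYPE,
            (H, F): CallClass.X,
            (H, Z): CallClass.Y,
        }
        for m in CovState:
            for f in CovState:
                calls = sa.classify_regions(seg("c", [m]), seg("c", [f]), 10_000)
                want = expected.get((m, f), CallClass.UNCLASSIFIED)
                assert calls[0].call is want, (m, f)

    @pytest.mark.parametrize(
        "male,female,call",
        [
            (H, F, CallClass.X),
            (H, Z, CallClass.Y),
            (F, F, CallClass.AUTOSOME),
            (H, H, CallClass.HAPLOTYPE),
        ],
    )
    def test_whole_contig_single_call(self, male, female, call):
        calls = sa.classify_regions(seg("c", [male] * 8), seg("c", [female] * 8), 10_000)
        assert len(calls) == 1
        assert calls[0].call is call
        assert (calls[0].start, calls[0].end) == (1, 80_000)

    def test_excess_in_either_sex_is_unclassified(self):
        calls = sa.classify_regions(seg("c", [E, F]), seg("c", [F, E]), 10_000)
        assert all(c.call is CallClass.UNCLASSIFIED for c in calls)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            sa.classify_regions(seg("c", [F, F]), seg("c", [F]), 10_000)
        with pytest.raises(ValueError):
            sa.classify_regions(seg("a", [F]), seg("b", [F]), 10_000)

    def test_adjacent_same_call_regions_merge(self):
        # AUTOSOME from (F,F) twice with a level change in between stays merged
        calls = sa.classify_regions(seg("c", [F, F, H, F]), seg("c", [F, F, F, F]), 10_000)
        assert [c.call for c in calls] == [CallClass.AUTOSOME, CallClass.X, CallClass.AUTOSOME]
        assert calls[0].end + 1 == calls[1].start

    def test_contig_length_trims_last_region(self):
        calls = sa.classify_regions(seg("c", [F, F]), seg("c", [F, F]), 10_000, contig_length=15_500)
        assert calls[0].end == 15_500

    def test_bed_round_trip(self, tmp_path):
        calls = sa.classify_regions(seg("c", [H, H, F]), seg("c", [F, Z, F]), 10_000)
        sa.write_region_calls(calls, tmp_path / "c.bed")
        back = sa.read_region_calls_bed(tmp_path / "c.bed")
        assert [(b.contig_id, b.start, b.end, b.call) for b in back] == [
            (c.contig_id, c.start, c.end, c.call) for c in calls
        ]


class TestSeparatePar:
    def _calls(self):
        return sa.classify_regions(
            seg("cx", [H, H, F, F]), seg("cx", [F, F, F, F]), 10_000
        )  # X then AUTOSOME

    def test_autosome_next_to_x_becomes_par(self):
        out = sa.separate_par(self._calls(), {"cx"})
        assert [c.call for c in out] == [CallClass.X, CallClass.PAR]

    def test_contig_outside_set_unchanged(self):
        out = sa.separate_par(self._calls(), set())
        assert [c.call for c in out] == [CallClass.X, CallClass.AUTOSOME]

    def test_pure_x_contig_gains_no_par(self):
        calls = sa.classify_regions(seg("cx", [H, H]), seg("cx", [F, F]), 10_000)
        out = sa.separate_par(calls, {"cx"})
        assert [c.call for c in out] == [CallClass.X]


class TestEmitMapMarkers:
    def test_30kb_y_region_gives_three_lg22_markers(self):
        calls = [sa.RegionCall("c", 1, 30_000, CallClass.Y, "50%", "0%")]
        markers = sa.emit_map_markers(calls, marker_spacing=10_000)
        assert len(markers) == 3
        assert all(m.linkage_group == "LG22" for m in markers)
        assert all(m.map_position_cM == 0.0 for m in markers)

    def test_x_and_par_feed_lg12(self):
        calls = [
            sa.RegionCall("c", 1, 10_000, CallClass.X, "50%", "100%"),
            sa.RegionCall("c", 10_001, 20_000, CallClass.PAR, "100%", "100%"),
        ]
        markers = sa.emit_map_markers(calls, marker_spacing=10_000)
        assert {m.linkage_group for m in markers} == {"LG12"}
        assert len(markers) == 2

    def test_autosome_only_yields_no_markers(self):
        calls = [sa.RegionCall("c", 1, 90_000, CallClass.AUTOSOME, "100%", "100%")]
        assert sa.emit_map_markers(calls) == []


class TestSummarizeAssignment:
    def test_perfect_calls_give_identity_confusion(self, small_layout):
        ws = small_layout.window_size
        truth_to_call = dict(sa._TRUTH_TO_CALL)
        calls = []
        for cid, labels in small_layout.window_classes.items():
            for w, cls in enumerate(labels):
                end = min((w + 1) * ws, small_layout.contig_lengths[cid])
                calls.append(
                    sa.RegionCall(cid, w * ws + 1, end, truth_to_call[cls], "", "")
                )
        summary = sa.summarize_assignment(calls, small_layout)
        conf = summary.confusion
        off_diag = conf.to_numpy().sum() - np.trace(conf.to_numpy())
        assert off_diag == 0
        for cls in ("AUTOSOME", "HAPLOTYPE", "X", "Y", "PAR"):
            assert summary.recall[cls] == 1.0
            assert summary.precision[cls] == 1.0

    def test_all_unclassified_gives_zero_recall(self, small_layout):
        calls = [
            sa.RegionCall(c.contig_id, 1, c.length, CallClass.UNCLASSIFIED, "", "")
            for c in small_layout.contigs
        ]
        summary = sa.summarize_assignment(calls, small_layout)
        for cls in ("AUTOSOME", "HAPLOTYPE", "X", "Y", "PAR"):
            assert summary.recall[cls] == 0.0

    def test_unknown_contig_rejected(self, small_layout):
        calls = [sa.RegionCall("nope", 1, 100, CallClass.X, "", "")]
        with pytest.raises(ValueError):
            sa.summarize_assignment(calls, small_layout)

    def test_y_recovery_monotone_in_dispersion(self):
        from sexscaff import coverage_model as cm

        layout = sd.generate_layout(
            {RegionClass.AUTOSOME: 6, RegionClass.Y: 3, RegionClass.X: 3},
            (150_000, 300_000), 10_000, seed=21,
        )
        recalls = []
        for disp in (20.0, 5.0):
            male = sd.simulate_depth(layout, Sex.MALE, 100, disp, seed=22)
            female = sd.simulate_depth(layout, Sex.FEMALE, 100, disp, seed=23)
            mm = cm.fit_emissions(male, 100)
            mf = cm.fit_emissions(female, 100)
            calls = []
            for tm, tf in zip(male, female):
                calls.extend(
                    sa.classify_regions(
                        cm.segment_track(tm, mm), cm.segment_track(tf, mf), 10_000
                    )
                )
            recalls.append(sa.summarize_assignment(calls, layout).recall["Y"])
        assert recalls[1] >= recalls[0]
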