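import numpy as np
import pandas as pd
import pytest

from memidr.idr import IDRInterval
from memidr.io import (
    TOPO_DOM,
    TRANSMEM,
    FeatureError,
    FeatureInterval,
    ProteinRecord,
    classify_pass_type,
)
from memidr.topology import (
    AMBIGUOUS,
    CYTOPLASMIC,
    EXTRACELLULAR,
    TM,
    UNKNOWN,
    build_topology,
    filter_undeterminable,
    length_statistics,
    localize,
    occupancy,
    occupancy_summary,
    occupancy_table,
    side_statistics,
)
from memidr.simulate import SimSpec, generate_proteome


def record(length, features):
    rec = ProteinRecord("P1", "A" * length)
    rec.attach_features(features)
    return rec


class TestBuildTopology:
    def test_fully_annotated_three_segments(self):
        rec = record(
            60,
            [
                FeatureInterval(TRANSMEM, 10, 30),
                FeatureInterval(TOPO_DOM, 1, 9, "Cytoplasmic"),
                FeatureInterval(TOPO_DOM, 31, 60, "Extracellular"),
            ],
        )
        model = build_topology(rec)
        assert [(s.start, s.end, s.side) for s in model.segments] == [
            (1, 9, CYTOPLASMIC),
            (10, 30, TM),
            (31, 60, EXTRACELLULAR),
        ]

    def test_alternation_inference(self):
        rec = record(
            60,
            [
                FeatureInterval(TRANSMEM, 10, 30),
                FeatureInterval(TOPO_DOM, 1, 9, "Cytoplasmic"),
            ],
        )
        model = build_topology(rec)
        assert model.segments[-1] .side == EXTRACELLULAR

    def test_same_side_across_tm_is_error(self):
        rec = record(
            60,
            [
                FeatureInterval(TRANSMEM, 10, 30),
                FeatureInterval(TOPO_DOM, 1, 9, "Cytoplasmic"),
                FeatureInterval(TOPO_DOM, 31, 60, "Cytoplasmic"),
            ],
        )
        with pytest.raises(FeatureError, match="alternation"):
            build_topology(rec)

    def test_topo_dom_overlapping_tm_is_error(self):
        rec = record(
            60,
            [
                FeatureInterval(TRANSMEM, 10, 30),
                FeatureInterval(TOPO_DOM, 25, 40, "Extracellular"),
            ],
        )
        with pytest.raises(FeatureError, match="overlaps"):
            build_topology(rec)

    def test_unannotated_loops_unknown(self):
        rec = record(60, [FeatureInterval(TRANSMEM, 10, 30)])
        model = build_topology(rec)
        assert {s.side for s in model.loops()} == {UNKNOWN}

    def test_lumenal_is_extracellular(self):
        rec = record(
            60,
            [
                FeatureInterval(TRANSMEM, 10, 30),
                FeatureInterval(TOPO_DOM, 31, 60, "Lumenal"),
            ],
        )
        model = build_topology(rec)
        assert model.segments[0].side == CYTOPLASMIC
        assert model.segments[-1].side == EXTRACELLULAR

    def test_tm_at_position_one(self):
        rec = record(
            60,
            [
                FeatureInterval(TRANSMEM, 1, 21),
                FeatureInterval(TOPO_DOM, 22, 60, "Cytoplasmic"),
            ],
        )
        model = build_topology(rec)
        assert model.segments[0].side == TM
        assert model.segments[1].side == CYTOPLASMIC

    def test_partition_property_on_synthetic(self):
        recs, truth = generate_proteome(SimSpec(seed=3, n_proteins=25))
        for rec in recs:
            model = build_topology(rec)
            # segments tile [1, L] without gaps or overlaps
            pos = 1
            for seg in model.segments:
                assert seg.start == pos
                pos = seg.end + 1
            assert pos == rec.length + 1
            # reconstruction matches the planted truth exactly
            planted = truth.proteins[rec.id].model
            assert [
                (s.start, s.end, s.side) for s in model.segments
            ] == [(s.start, s.end, s.side) for s in planted.segments]


class TestLocalize:
    def _model(self):
        rec = record(
            100,
            [
                FeatureInterval(TRANSMEM, 41, 60),
                FeatureInterval(TOPO_DOM, 1, 40, "Cytoplasmic"),
                FeatureInterval(TOPO_DOM, 61, 100, "Extracellular"),
            ],
        )
        return build_topology(rec)

    def test_fully_cytoplasmic(self):
        a = localize(self._model(), 5, 30)
        assert a.side == CYTOPLASMIC
        assert a.overlap_fraction == 1.0

    def test_majority_across_tm(self):
        # 25 cytoplasmic (16..40), 20 TM, 5 extracellular (61..65)
        a = localize(self._model(), 16, 65)
        assert a.side == CYTOPLASMIC
        assert np.isclose(a.overlap_fraction, 25 / 50)

    def test_exact_tie_is_ambiguous(self):
        # 10 residues either side of the TM
        a = localize(self._model(), 31, 70)
        assert a.side == AMBIGUOUS

    def test_all_tm_is_ambiguous(self):
        assert localize(self._model(), 45, 55).side == AMBIGUOUS

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            localize(self._model(), 90, 120)


class TestFilterUndeterminable:
    def _multi(self, pid, loop_len):
        rec = ProteinRecord(pid, "A" * (loop_len * 3 + 42))
        tm1 = (loop_len + 1, loop_len + 21)
        tm2 = (2 * loop_len + 22, 2 * loop_len + 42)
        rec.attach_features(
            [FeatureInterval(TRANSMEM, *tm1), FeatureInterval(TRANSMEM, *tm2)]
        )
        return rec

    def test_all_short_loops_excluded(self):
        rec = self._multi("P1", 20)
        kept, excluded = filter_undeterminable(
            [rec], {"P1": build_topology(rec)}
        )
        assert kept == [] and excluded == ["P1"]

    def test_one_long_loop_retained(self):
        rec = self._multi("P1", 40)
        kept, excluded = filter_undeterminable(
            [rec], {"P1": build_topology(rec)}
        )
        assert kept == [rec] and excluded == []

    def test_single_pass_always_retained(self):
        rec = ProteinRecord("P1", "A" * 40)
        rec.attach_features([FeatureInterval(TRANSMEM, 11, 31)])
        assert classify_pass_type(rec) == "single-pass"
        kept, excluded = filter_undeterminable(
            [rec], {"P1": build_topology(rec)}
        )
        assert kept == [rec]


class TestSideStatistics:
    def _assignments(self, n_cyto, n_extra, pid="P1"):
        from memidr.topology import SideAssignment

        out = [
            SideAssignment(pid, 1, 30, CYTOPLASMIC, 1.0) for _ in range(n_cyto)
        ]
        out += [
            SideAssignment(pid, 1, 30, EXTRACELLULAR, 1.0)
            for _ in range(n_extra)
        ]
        return out

    def test_printed_multipass_counts(self):
        df = side_statistics(
            self._assignments(669, 157), {"P1": "multi-pass"}
        )
        assert df.n_cytoplasmic[0] == 669
        assert round(df.pct_cytoplasmic[0]) == 81

    def test_all_cytoplasmic(self):
        df = side_statistics(self._assignments(5, 0), {"P1": "single-pass"})
        assert df.pct_cytoplasmic[0] == 100.0

    def test_even_split(self):
        df = side_statistics(self._assignments(1, 1), {"P1": "single-pass"})
        assert df.pct_cytoplasmic[0] == df.pct_extracellular[0] == 50.0

    def test_percentages_sum_to_100(self):
        df = side_statistics(self._assignments(7, 3), {"P1": "multi-pass"})
        assert np.isclose(df.pct_cytoplasmic[0] + df.pct_extracellular[0], 100.0)


class TestOccupancy:
    def _model(self, cyto_len=100):
        rec = record(
            cyto_len + 60,
            [
                FeatureInterval(TRANSMEM, cyto_len + 1, cyto_len + 20),
                FeatureInterval(TOPO_DOM, 1, cyto_len, "Cytoplasmic"),
                FeatureInterval(
                    TOPO_DOM, cyto_len + 21, cyto_len + 60, "Extracellular"
                ),
            ],
        )
        return build_topology(rec)

    def test_full_coverage(self):
        occ = occupancy(self._model(), [IDRInterval("P1", 1, 100)])
        assert occ[CYTOPLASMIC] == 100.0

    def test_direct_ratio(self):
        occ = occupancy(self._model(), [IDRInterval("P1", 10, 70)])
        assert occ[CYTOPLASMIC] == 61.0

    def test_no_idrs(self):
        occ = occupancy(self._model(), [])
        assert occ[CYTOPLASMIC] == 0.0
        assert occ[EXTRACELLULAR] == 0.0

    def test_conservation_per_side(self):
        model = self._model()
        idrs = [IDRInterval("P1", 5, 44), IDRInterval("P1", 50, 89)]
        occ = occupancy(model, idrs)
        sides = model.side_array()
        covered = np.zeros(model.length, bool)
        for iv in idrs:
            covered[iv.start - 1 : iv.end] = True
        outside = 100.0 * ((sides == CYTOPLASMIC) & ~covered).sum() / (
            sides == CYTOPLASMIC
        ).sum()
        assert np.isclose(occ[CYTOPLASMIC] + outside, 100.0)

    def test_summary_mean_and_sem(self):
        model = self._model()
        table = occupancy_table(
            {"P1": model}, {"P1": [IDRInterval("P1", 1, 50)]}, {"P1": "single-pass"}
        )
        summ = occupancy_summary(table)
        row = summ[summ.side == CYTOPLASMIC].iloc[0]
        assert row.mean_pct == 50.0
        assert row.sem_pct == 0.0


class TestLengthStatistics:
    def _assign(self, pid, start, end, side):
        from memidr.topology import SideAssignment

        return SideAssignment(pid, start, end, side, 1.0)

    def test_median_of_three(self):
        assignments = [
            self._assign("P1", 1, 30, CYTOPLASMIC),
            self._assign("P1", 1, 40, CYTOPLASMIC),
            self._assign("P1", 1, 50, CYTOPLASMIC),
        ]
        df = length_statistics(assignments, {"P1": "single-pass"})
        assert df["median"][0] == 40

    def test_single_idr(self):
        df = length_statistics(
            [self._assign("P1", 1, 42, CYTOPLASMIC)], {"P1": "multi-pass"}
        )
        assert df["median"][0] == 42

    def test_oracle_group_by(self, rng):
        sides = [CYTOPLASMIC, EXTRACELLULAR]
        pts = ["single-pass", "multi-pass"]
        assignments, pass_types = [], {}
        raw = []
        for i in range(200):
            pid = f"P{i}"
            pt = pts[int(rng.integers(2))]
            side = sides[int(rng.integers(2))]
            length = int(rng.integers(30, 200))
            pass_types[pid] = pt
            assignments.append(self._assign(pid, 1, length, side))
            raw.append((pt, side, length))
        df = length_statistics(assignments, pass_types).set_index(
            ["pass_type", "side"]
        )
        oracle = {}
        for pt, side, length in raw:
            oracle.setdefault((pt, side), []).append(length)
        for key, lengths in oracle.items():
            row = df.loc[key]
            assert row["n"] == len(lengths)
            assert np.isclose(row["mean"], np.mean(lengths))
            assert np.isclose(row["median"], np.median(lengths))
            assert np.isclose(row["q1"], np.quantile(lengths, 0.25))

    def test_empty_assignments(self):
        df = length_statistics([], {})
        assert df.empty
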