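"""Episode IO, baseline selection and per-patient aggregation."""

import random
from datetime import date

import pytest

from hhpheno.codesets import CodeSystem, normalize_code
from hhpheno.cohort import (
    Episode,
    GoldCategory,
    RowParseError,
    SchemaError,
    aggregate_patients,
    parse_category,
    read_episodes,
    read_gold_labels,
    select_baseline,
    write_episodes,
)


def _episode(pid, eid, diagnoses=(), procedures=(), day=date(2019, 6, 1), age=50, sex="F"):
    return Episode(
        patient_id=pid,
        episode_id=eid,
        admission_date=day,
        age_at_admission=age,
        sex=sex,
        diagnoses=tuple(normalize_code(c, CodeSystem.ICD10) for c in diagnoses),
        procedures=tuple(normalize_code(c, CodeSystem.OPCS4) for c in procedures),
    )


EPISODES_CSV = """patient_id,episode_id,admidate,startage,sex,diag_01,diag_02,opertn_01
P1,E1,2019-01-02,64,M,E831,,X362
P1,E2,2019-02-03,64,M,E83.1,D45,
P2,E1,2020-07-14,41,F,K219,,
"""


class TestReadEpisodes:
    def test_reads_rows_and_codes(self, tmp_path):
        path = tmp_path / "eps.csv"
        path.write_text(EPISODES_CSV)
        episodes = read_episodes(path)
        assert len(episodes) == 3
        assert len({e.patient_id for e in episodes}) == 2
        first = episodes[0]
        assert [c.normalized for c in first.diagnoses] == ["E831"]
        assert [c.normalized for c in first.procedures] == ["X362"]
        # blank cells skipped, dotted spelling normalised
        assert [c.normalized for c in episodes[1].diagnoses] == ["E831", "D45"]

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,episode_id,admidate,startage,diag_01\nP1,E1,2019-01-01,40,E831\n")
        with pytest.raises(SchemaError, match="sex"):
            read_episodes(path)

    def test_bad_date_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(EPISODES_CSV.replace("2020-07-14", "14/07/2020"))
        with pytest.raises(RowParseError, match="row 2"):
            read_episodes(path)

    def test_roundtrip_through_writer(self, tmp_path):
        path = tmp_path / "eps.csv"
        eps = [
            _episode("P1", "E1", ["E83.1", "C911"], ["X36.2"]),
            _episode("P2", "E1", ["D56"], [], age=30, sex="M"),
        ]
        write_episodes(eps, path)
        back = read_episodes(path)
        assert [
            (e.patient_id, [c.normalized for c in e.diagnoses],
             [c.normalized for c in e.procedures])
            for e in back
        ] == [("P1", ["E831", "C911"], ["X362"]), ("P2", ["D56"], [])]


class TestSelectBaseline:
    def test_requires_e831_and_age(self):
        eps = [
            _episode("A", "E1", ["E831"]),
            _episode("B", "E1", ["D45"]),          # no qualifying diagnosis
            _episode("C", "E1", ["E831"], age=17),  # under age
        ]
        kept = select_baseline(eps)
        assert {e.patient_id for e in kept} == {"A"}

    def test_keeps_all_episodes_of_qualifying_patients(self):
        eps = [
            _episode("A", "E1", ["E831"]),
            _episode("A", "E2", ["K219"]),  # retained for feature building
        ]
        assert len(select_baseline(eps)) == 2

    def test_window_filtering(self):
        eps = [
            _episode("A", "E1", ["E831"], day=date(2017, 1, 1)),  # pre-window
            _episode("B", "E1", ["E831"], day=date(2018, 4, 1)),  # boundary in
        ]
        assert {e.patient_id for e in select_baseline(eps)} == {"B"}


class TestAggregatePatients:
    def test_venesection_counts_episodes_not_codes(self):
        eps = [
            _episode("A", "E1", ["E831"], ["X362", "X36.2"]),  # one episode, counts once
            _episode("A", "E2", ["E831"], ["X362"]),
            _episode("A", "E3", ["E831"]),
        ]
        (rec,) = aggregate_patients(eps)
        assert rec.venesection_episodes == 2
        assert rec.n_episodes == 3
        assert rec.has_e831

    def test_group_flags_any_position_any_episode(self):
        eps = [
            _episode("A", "E1", ["E831", "D561"]),  # secondary G2 child code
            _episode("A", "E2", ["E801"]),          # G1 (porphyria cutanea tarda)
        ]
        (rec,) = aggregate_patients(eps)
        assert rec.has_g1_code and rec.has_g2_code

    def test_duplicates_removed_with_warning(self, caplog):
        eps = [_episode("A", "E1", ["E831"]), _episode("A", "E1", ["E831"])]
        with caplog.at_level("WARNING"):
            (rec,) = aggregate_patients(eps)
        assert rec.n_episodes == 1
        assert "duplicate" in caplog.text

    def test_order_invariance_and_episode_conservation(self, cohort):
        episodes = list(cohort.episodes)
        base = aggregate_patients(episodes)
        assert sum(r.n_episodes for r in base) == len(episodes)
        shuffled = episodes[:]
        random.Random(99).shuffle(shuffled)
        assert aggregate_patients(shuffled) == base

    def test_age_at_first_episode_uses_earliest_date(self):
        eps = [
            _episode("A", "E2", ["E831"], day=date(2021, 1, 1), age=67),
            _episode("A", "E1", ["K219"], day=date(2019, 1, 1), age=65),
        ]
        (rec,) = aggregate_patients(eps)
        assert rec.age_at_first_episode == 65


class TestGoldLabels:
    def test_reads_display_and_enum_names(self, tmp_path):
        path = tmp_path / "labels.csv"
        path.write_text(
            "patient_id,category\nP1,C282Y/C282Y\nP2,HYPERFERRITINAEMIA\nP3,Incorrect coding\n"
        )
        lab = read_gold_labels(path)
        assert [l.category for l in lab] == [
            GoldCategory.C282Y_HOM,
            GoldCategory.HYPERFERRITINAEMIA,
            GoldCategory.INCORRECT_CODING,
        ]
        assert lab[0].is_positive and not lab[1].is_positive

    def test_unknown_category_lists_valid(self, tmp_path):
        path = tmp_path / "labels.csv"
        path.write_text("patient_id,category\nP1,banana\n")
        with pytest.raises(ValueError, match="C282Y_HOM"):
            read_gold_labels(path)

    def test_duplicate_patient_rejected(self, tmp_path):
        path = tmp_path / "labels.csv"
        path.write_text("patient_id,category\nP1,C282Y/C282Y\nP1,C282Y/H63D\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gold_labels(path)

    def test_parse_category_display_spellings(self):
        assert parse_category("C282Y/C282Y") is GoldCategory.C282Y_HOM
        assert parse_category("Porphyria cutanea tarda") is GoldCategory.PCT
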