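"""Survey container: validation, I/O round trip, aggregation, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disturbsamp import (SurveyValidationError, aggregate_observer_counts,
                         read_survey, summarize_by_passage, write_survey)
from disturbsamp.simulate import SimulationConfig, simulate_survey

from conftest import make_dataset


class TestValidation:
    def test_valid_dataset_constructs(self, tiny_dataset):
        assert tiny_dataset.n_walks() == 7
        assert len(tiny_dataset.observations) == 5
        assert len(tiny_dataset.heard) == 4

    @pytest.mark.parametrize("row, match", [
        (("C", 2, "g9", "sp1", 100.0, 2, 3.0), "orphan"),
        (("A", 2, "g9", "sp1", 100.0, 5, 3.0), "estimated_size"),
        (("A", 2, "g9", "sp1", -5.0, 2, 3.0), "negative"),
        (("A", 2, "g9", "sp1", 100.0, 0, 3.0), "observed_size"),
    ])
    def test_bad_observation_rows_are_named(self, tiny_dataset, row, match):
        obs = pd.concat([tiny_dataset.observations,
                         pd.DataFrame([row], columns=tiny_dataset.observations.columns)])
        with pytest.raises(SurveyValidationError, match=match):
            make_dataset(tiny_dataset.transects.itertuples(index=False),
                         obs.itertuples(index=False),
                         tiny_dataset.heard.itertuples(index=False))

    @pytest.mark.parametrize("row, match", [
        (("A", 9, 1.0, "morning", 0.0), "unknown passage"),
        (("A", 2, 0.0, "morning", 0.0), "effort"),
        (("A", 2, 1.0, "noon", 0.0), "time_of_day"),
        (("A", 2, 1.0, "morning", 2.0), "passage 2"),
        (("C", 4, 1.0, "morning", 1.0), "passage 4"),
        (("A", 2, 1.0, "afternoon", 0.0), "duplicate"),
    ])
    def test_bad_transect_rows_are_named(self, tiny_dataset, row, match):
        t = pd.concat([tiny_dataset.transects,
                       pd.DataFrame([row], columns=tiny_dataset.transects.columns)])
        with pytest.raises(SurveyValidationError, match=match):
            make_dataset(t.itertuples(index=False))

    def test_missing_column_and_non_numeric(self, tiny_dataset):
        from disturbsamp.survey import SurveyDataset
        t = tiny_dataset.transects.drop(columns=["effort_km"])
        with pytest.raises(SurveyValidationError, match="missing column"):
            SurveyDataset(t, tiny_dataset.observations.iloc[:0], tiny_dataset.heard.iloc[:0])
        t2 = tiny_dataset.transects.copy()
        t2["effort_km"] = t2["effort_km"].astype(object)
        t2.loc[0, "effort_km"] = "abc"
        with pytest.raises(SurveyValidationError, match="non-numeric"):
            SurveyDataset(t2, tiny_dataset.observations.iloc[:0], tiny_dataset.heard.iloc[:0])

    def test_unknown_heard_category(self, tiny_dataset):
        with pytest.raises(SurveyValidationError, match="category"):
            make_dataset(tiny_dataset.transects.itertuples(index=False),
                         heard=[("A", 2, "sp1", "nearby")])


class TestIO:
    def test_round_trip_is_identity(self, tiny_dataset, tmp_path):
        paths = write_survey(tiny_dataset, tmp_path)
        ds2 = read_survey(paths["transects"], paths["observations"], paths["heard"])
        pd.testing.assert_frame_equal(tiny_dataset.transects, ds2.transects)
        pd.testing.assert_frame_equal(tiny_dataset.observations, ds2.observations)
        pd.testing.assert_frame_equal(tiny_dataset.heard, ds2.heard)

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_survey(tmp_path / "x.csv", tmp_path / "y.csv", tmp_path / "z.csv")


class TestAggregateObserverCounts:
    @pytest.mark.parametrize("obs, est, expected", [
        ((3, 5, 4, 4), (6, 8, 7, 7), (5, 7.0)),
        ((4,), (4,), (4, 4.0)),
        ((5, 5, 5, 5), (2, 2, 2, 2), (5, 5.0)),  # floored at best direct count
    ])
    def test_rules(self, obs, est, expected):
        assert aggregate_observer_counts(obs, est) == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_observer_counts([], [])

    @given(st.data(), st.lists(st.integers(0, 50), min_size=1, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, data, counts):
        est = [c + 1.5 for c in counts]
        perm = data.draw(st.permutations(range(len(counts))))
        assert aggregate_observer_counts([counts[i] for i in perm],
                                         [est[i] for i in perm]) == \
            aggregate_observer_counts(counts, est)


class TestSummary:
    def test_tiny_summary_counts(self, tiny_dataset):
        s = summarize_by_passage(tiny_dataset)
        total = s[s.passage == "Total"].iloc[0]
        per = s[s.passage != "Total"]
        # conservation: totals equal the sum of per-passage values
        assert total.n_transects == per.n_transects.sum() == 7
        assert total.effort_km == pytest.approx(per.effort_km.sum())
        for col in ("heard_close", "heard_far", "heard_very_far"):
            assert total[col] == per[col].sum()
        assert (total.heard_close + total.heard_far + total.heard_very_far
                == len(tiny_dataset.heard))
        # poly group g2 counts once: P3 has 2 group events + 1 heard over 1.8 km
        p3 = s[s.passage == "P3"].iloc[0]
        assert p3.encounter_rate == pytest.approx(3 / 1.8)
        assert p3.poly_encounter_rate == pytest.approx(1 / 1.8)
        assert total.encounter_rate >= total.poly_encounter_rate >= 0

    def test_empty_dataset_gives_zero_summary(self):
        s = summarize_by_passage(make_dataset([]))
        total = s.iloc[-1]
        assert total.n_transects == 0 and total.effort_km == 0
        assert total.encounter_rate == 0

    def test_conservation_on_simulated_survey(self):
        ds = simulate_survey(SimulationConfig(n_transects=50), seed=5)
        s = summarize_by_passage(ds)
        per, total = s.iloc[:-1], s.iloc[-1]
        assert total.n_transects == per.n_transects.sum()
        assert total.effort_km == pytest.approx(per.effort_km.sum())
        assert (per.heard_close.sum() + per.heard_far.sum()
                + per.heard_very_far.sum()) == len(ds.heard)
        # both grand-average conventions are exposed
        assert set(s.attrs) >= {"encounter_rate_effort_weighted",
                                "encounter_rate_passage_mean"}
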