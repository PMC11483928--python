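"""Line-of-therapy derivation: timelines, transition rules, labelling."""

import itertools

import pandas as pd
import pytest

from gpp_journey.lot import (
    build_regimen_timeline,
    derive_lots,
    label_regimen,
)


def day(n: int) -> pd.Timestamp:
    return pd.Timestamp("2017-01-01") + pd.Timedelta(days=n)


def eps_frame(rows):
    """rows: (category2, is_supplementary, start_day, end_day)"""
    df = pd.DataFrame(rows, columns=["category2", "is_supplementary", "s", "e"])
    df["start"] = df["s"].map(day)
    df["end"] = df["e"].map(day)
    return df[["category2", "is_supplementary", "start", "end"]]


def lots_for(rows, config, catalog, fend=1000):
    timeline = build_regimen_timeline(eps_frame(rows), day(0), day(fend))
    return derive_lots(timeline, "A", catalog, config)


class TestTimeline:
    def test_single_episode_one_state(self):
        tl = build_regimen_timeline(eps_frame([("Etretinate", False, 0, 100)]),
                                    day(0), day(100))
        assert len(tl) == 1
        assert tl[0].main == {"Etretinate"} and not tl[0].supp

    def test_overlapping_supplementary_splits_three_states(self):
        tl = build_regimen_timeline(
            eps_frame([("Etretinate", False, 0, 100), ("Topical therapy", True, 20, 80)]),
            day(0), day(100))
        assert [(set(s.main), set(s.supp)) for s in tl] == [
            ({"Etretinate"}, set()),
            ({"Etretinate"}, {"Topical therapy"}),
            ({"Etretinate"}, set()),
        ]
        # states tile the window
        assert tl[0].start == day(0) and tl[-1].end == day(100)
        assert all(a.end == b.start for a, b in zip(tl, tl[1:]))

    def test_no_episodes_single_untreated_state(self):
        tl = build_regimen_timeline(eps_frame([]), day(0), day(100))
        assert len(tl) == 1
        assert not tl[0].main and not tl[0].supp

    def test_episodes_trimmed_to_window(self):
        tl = build_regimen_timeline(
            eps_frame([("Etretinate", False, -50, 30), ("Cyclosporin", False, 90, 200)]),
            day(0), day(100))
        assert tl[0].start == day(0)
        assert tl[-1].end == day(100)


class TestDeriveLots:
    def test_switch_after_discontinuation(self, catalog, config):
        # etretinate ends, cyclosporin starts 100 days later (> oral gap)
        lots = lots_for([("Etretinate", False, 0, 100),
                         ("Cyclosporin", False, 200, 300)], config, catalog)
        assert [l.general_regimen for l in lots] == ["Etretinate", "Cyclosporin"]
        assert lots[0].end == day(100)  # closed at last coverage end
        assert lots[1].start == day(200)

    def test_seamless_switch(self, catalog, config):
        lots = lots_for([("Etretinate", False, 0, 100),
                         ("Cyclosporin", False, 100, 200)], config, catalog)
        assert [l.general_regimen for l in lots] == ["Etretinate", "Cyclosporin"]
        assert lots[0].end == lots[1].start == day(100)

    def test_start_within_window_joins_combination(self, catalog, config):
        lots = lots_for([("Etretinate", False, 0, 200),
                         ("IL-17 inhibitors", False, 10, 200)], config, catalog)
        assert len(lots) == 1
        assert lots[0].main_categories == {"Etretinate", "IL-17 inhibitors"}
        assert lots[0].general_regimen == "IL-17 inhibitors"
        assert lots[0].start == day(0)

    def test_late_start_is_add_on_new_lot(self, catalog, config):
        lots = lots_for([("Etretinate", False, 0, 200),
                         ("IL-17 inhibitors", False, 60, 200)], config, catalog)
        assert len(lots) == 2
        assert lots[0].main_categories == {"Etretinate"}
        assert lots[1].main_categories == {"Etretinate", "IL-17 inhibitors"}
        assert lots[1].start == day(60)

    def test_component_discontinuation_opens_new_lot(self, catalog, config):
        lots = lots_for([("Etretinate", False, 0, 200),
                         ("Cyclosporin", False, 0, 100)], config, catalog)
        assert len(lots) == 2
        assert lots[0].main_categories == {"Cyclosporin", "Etretinate"}
        assert lots[1].main_categories == {"Etretinate"}
        assert lots[1].start == day(100)

    def test_supplementary_never_changes_main_lot(self, catalog, config):
        lots = lots_for([("Etretinate", False, 0, 200),
                         ("Topical therapy", True, 50, 120)], config, catalog)
        assert len(lots) == 1
        assert lots[0].specific_regimen == "Etretinate + supplementary drug"
        assert lots[0].general_regimen == "Etretinate"

    def test_supplementary_only_period_is_its_own_lot(self, catalog, config):
        lots = lots_for([("Topical therapy", True, 0, 100)], config, catalog, fend=200)
        assert len(lots) == 1
        assert lots[0].general_regimen == "Topical therapy"
        assert not lots[0].main_categories

    def test_supplementary_tail_after_main_becomes_new_lot(self, catalog, config):
        lots = lots_for([("Etretinate", False, 0, 100),
                         ("Topical therapy", True, 50, 250)], config, catalog, fend=300)
        assert [l.general_regimen for l in lots] == ["Etretinate", "Topical therapy"]
        assert lots[1].start == day(100)

    def test_short_untreated_gap_keeps_lot_open(self, catalog, config):
        # 40-day hole between two etretinate category spells (same regimen):
        # below the 61-day oral limit, the line continues (one line)
        lots = lots_for([("Etretinate", False, 0, 100),
                         ("Etretinate", False, 140, 240)], config, catalog, fend=240)
        assert len(lots) == 1
        assert lots[0].start == day(0)

    def test_long_untreated_gap_closes_lot_even_for_same_regimen(self, catalog, config):
        lots = lots_for([("Etretinate", False, 0, 100),
                         ("Etretinate", False, 200, 300)], config, catalog, fend=300)
        assert len(lots) == 2
        assert lots[0].end == day(100)

    def test_last_lot_open_to_followup_end(self, catalog, config):
        lots = lots_for([("Etretinate", False, 0, 100)], config, catalog, fend=120)
        assert lots[0].is_last
        assert lots[0].end == day(120)

    def test_lot_numbers_consecutive_and_starts_increasing(self, catalog, config):
        lots = lots_for([("Etretinate", False, 0, 100),
                         ("Cyclosporin", False, 200, 300),
                         ("IL-17 inhibitors", False, 420, 520)], config, catalog, fend=600)
        assert [l.lot_number for l in lots] == [1, 2, 3]
        starts = [l.start for l in lots]
        assert starts == sorted(starts) and len(set(starts)) == 3

    def test_input_order_irrelevant(self, catalog, config):
        rows = [("Etretinate", False, 0, 100), ("Cyclosporin", False, 200, 300),
                ("Topical therapy", True, 210, 260)]
        a = lots_for(rows, config, catalog)
        b = lots_for(rows[::-1], config, catalog)
        assert [(l.start, l.specific_regimen) for l in a] == \
               [(l.start, l.specific_regimen) for l in b]


class TestLabelRegimen:
    def test_lowest_priority_number_wins(self, catalog):
        general, _ = label_regimen({"Etretinate", "Cyclosporin"}, False, catalog)
        assert general == "Etretinate"
        general, _ = label_regimen({"IL-17 inhibitors", "Etretinate"}, False, catalog)
        assert general == "IL-17 inhibitors"

    def test_specific_label_sorted_with_suffix(self, catalog):
        _, specific = label_regimen({"Etretinate", "Cyclosporin"}, True, catalog)
        assert specific == "Cyclosporin + Etretinate + supplementary drug"
        _, specific = label_regimen({"Etretinate"}, True, catalog)
        assert specific == "Etretinate + supplementary drug"

    def test_supplementary_only_promotes_best_ranked(self, catalog):
        general, specific = label_regimen(
            set(), {"Topical therapy", "Arthritis treatment"}, catalog)
        assert general == "Topical therapy"
        assert specific == "Topical therapy + supplementary drug"

    def test_empty_regimen_rejected(self, catalog):
        with pytest.raises(ValueError):
            label_regimen(set(), False, catalog)

    def test_apheresis_override(self, catalog):
        main = {"Apheresis/plasma exchange", "Cyclosporin"}
        assert label_regimen(main, False, catalog)[0] == "Cyclosporin"
        assert label_regimen(main, False, catalog, apheresis_dominates=True)[0] == \
            "Apheresis/plasma exchange"

    def test_agrees_with_exhaustive_argmin_oracle(self, catalog):
        """Priority labelling equals brute-force argmin over every non-empty
        subset of the twelve categories."""
        cats = sorted(catalog.priority_table)
        for r in range(1, 4):  # all subsets up to size 3, plus the full set
            for subset in itertools.combinations(cats, r):
                expected = min(subset, key=lambda c: catalog.priority_table[c])
                assert label_regimen(set(subset), False, catalog)[0] == expected
        full = set(cats)
        assert label_regimen(full, False, catalog)[0] == "IL-17 inhibitors"
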