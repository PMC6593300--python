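"""Profile scoring, mortality-adjusted quartiles, level assignment
(algorithm step 2)."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from ipp.admin_records import ObservationWindow
from ipp.classifier import CATEGORIES, CHRONIC_CATEGORIES
from ipp.stratifier import (
    Level,
    LevelCutpoints,
    assign_complexity_level,
    category_weight,
    chronic_level_cutpoints,
    mortality_adjusted_scores,
    profile_score,
)

CHRONIC_BY_RANK = {c.rank: c.name for c in CATEGORIES if c.is_chronic}
WINDOW = ObservationWindow(2013, 2014)


class TestWeights:
    def test_binary_positional_weights(self):
        assert category_weight(1) == 65536
        assert category_weight(17) == 1
        assert category_weight(7) == 1024

    @pytest.mark.parametrize("rank", range(1, 17))
    def test_single_category_outweighs_all_less_severe(self, rank):
        assert category_weight(rank) > sum(
            category_weight(r) for r in range(rank + 1, 18))

    @pytest.mark.parametrize("rank", [0, 18, -3])
    def test_rank_out_of_range(self, rank):
        with pytest.raises(ValueError):
            category_weight(rank)


class TestProfileScore:
    def test_empty_profile_scores_zero(self):
        assert profile_score(frozenset()) == 0

    def test_worked_comorbidity_inequality(self):
        """Cardiovascular + neoplasm + gastro outranks cardiovascular +
        COPD + gastro."""
        a = profile_score({"cardiovascular", "neoplasm", "gastro_enteropathy"})
        b = profile_score({"cardiovascular", "copd", "gastro_enteropathy"})
        assert (a, b) == (1344, 448)
        assert a > b

    def test_non_chronic_category_rejected(self):
        with pytest.raises(ValueError, match="not chronic"):
            profile_score({"pregnancy"})

    @given(st.sets(st.sampled_from(sorted(CHRONIC_CATEGORIES)), min_size=1),
           st.sampled_from(sorted(CHRONIC_CATEGORIES)))
    @settings(deadline=None)
    def test_adding_a_category_strictly_increases_score(self, cats, extra):
        if extra in cats:
            cats = cats - {extra}
        if cats:
            assert profile_score(cats | {extra}) > profile_score(cats)

    @given(st.sets(st.sampled_from(sorted(CHRONIC_CATEGORIES))),
           st.sets(st.sampled_from(sorted(CHRONIC_CATEGORIES))))
    @settings(deadline=None)
    def test_score_is_a_bijection_of_the_category_set(self, a, b):
        if a != b:
            assert profile_score(a) != profile_score(b)

    def test_severity_dominance(self):
        """Swapping any profile member for a strictly more severe unused
        category strictly increases the score."""
        rng = random.Random(4)
        ranks = sorted(CHRONIC_BY_RANK)
        for _ in range(200):
            members = rng.sample(ranks, k=rng.randrange(1, 6))
            profile = {CHRONIC_BY_RANK[r] for r in members}
            victim = rng.choice(members)
            better = [r for r in ranks if r < victim and r not in members]
            if not better:
                continue
            swap = rng.choice(better)
            upgraded = profile - {CHRONIC_BY_RANK[victim]} | {CHRONIC_BY_RANK[swap]}
            assert profile_score(upgraded) > profile_score(profile)


class TestMortalityAdjustment:
    def test_zero_mortality_is_identity(self):
        p = frozenset({"copd"})
        adj = mortality_adjusted_scores({"a": p, "b": p}, {"a": False, "b": False})
        assert adj[p] == profile_score(p)

    def test_quarter_mortality_scales_by_1_25(self):
        """Score-448 profile with 1 of 4 carriers dead adjusts to 560."""
        p = frozenset({"cardiovascular", "copd", "gastro_enteropathy"})
        profiles = {s: p for s in "abcd"}
        adj = mortality_adjusted_scores(profiles, {"a": True})
        assert adj[p] == pytest.approx(560.0)

    def test_monotone_in_mortality_at_fixed_score(self):
        p = frozenset({"diabetes"})
        low = mortality_adjusted_scores({s: p for s in "abcd"}, {"a": True})[p]
        high = mortality_adjusted_scores({s: p for s in "abcd"},
                                         {"a": True, "b": True})[p]
        assert high > low

    def test_non_chronic_subjects_do_not_contribute(self):
        p = frozenset({"diabetes"})
        adj = mortality_adjusted_scores({"a": p, "b": frozenset()},
                                        {"a": False, "b": True})
        assert set(adj) == {p}


class TestCutpoints:
    def test_linear_interpolation_quartiles(self):
        cuts = chronic_level_cutpoints({frozenset({c}): s for c, s in
                                        zip("wxyz", [1.0, 2.0, 3.0, 4.0])})
        assert (cuts.q1, cuts.q2, cuts.q3) == (1.75, 2.5, 3.25)

    def test_single_profile_degenerates_to_chronic_i(self):
        cuts = chronic_level_cutpoints([448.0])
        assert cuts.q1 == cuts.q2 == cuts.q3 == 448.0
        assert cuts.chronic_level(448.0) is Level.CHRONIC_I

    def test_invariant_under_subject_duplication(self):
        """Cut-points are a distinct-profile statistic: extra carriers of
        an existing profile change nothing."""
        profiles = {f"s{i}": frozenset({CHRONIC_BY_RANK[9 + i]}) for i in range(4)}
        base = chronic_level_cutpoints(mortality_adjusted_scores(profiles, {}))
        dup = dict(profiles, extra=profiles["s0"], extra2=profiles["s0"])
        dup_cuts = chronic_level_cutpoints(mortality_adjusted_scores(dup, {}))
        assert (base.q1, base.q2, base.q3) == (dup_cuts.q1, dup_cuts.q2, dup_cuts.q3)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            chronic_level_cutpoints([])


class TestLevelAssignment:
    CUTS = LevelCutpoints(100.0, 200.0, 300.0)

    def _assign(self, profile=frozenset(), years=(0, 0), died=False, adj=None):
        admissions = dict(zip(WINDOW.years, years))
        adjusted = {profile: adj} if profile else None
        return assign_complexity_level("s", profile, admissions, died,
                                       self.CUTS if profile else None,
                                       adjusted, WINDOW)

    def test_no_evidence_is_healthy(self):
        assert self._assign().level is Level.HEALTHY

    def test_death_without_chronic_profile_is_acute(self):
        assert self._assign(died=True).level is Level.DEATH_ACUTE

    def test_admissions_in_one_vs_both_years(self):
        assert self._assign(years=(1, 0)).level is Level.EARLY_SYMPTOMS
        assert self._assign(years=(0, 2)).level is Level.EARLY_SYMPTOMS
        assert self._assign(years=(1, 1)).level is Level.FIRST_DIAGNOSTIC

    def test_single_year_window_uses_repeat_admissions(self):
        w = ObservationWindow(2013, 2013)
        one = assign_complexity_level("s", frozenset(), {2013: 1}, False, None, None, w)
        two = assign_complexity_level("s", frozenset(), {2013: 2}, False, None, None, w)
        assert one.level is Level.EARLY_SYMPTOMS
        assert two.level is Level.FIRST_DIAGNOSTIC

    def test_chronic_levels_partition_by_adjusted_score(self):
        p = frozenset({"diabetes"})
        for adj, expected in [(100.0, Level.CHRONIC_I), (150.0, Level.CHRONIC_II),
                              (200.0, Level.CHRONIC_II), (300.0, Level.CHRONIC_III),
                              (301.0, Level.CHRONIC_IV)]:
            assert self._assign(p, adj=adj).level is expected

    def test_chronic_death_is_terminal_with_origin(self):
        p = frozenset({"neoplasm"})
        a = self._assign(p, died=True, adj=350.0)
        assert a.level is Level.TERMINAL
        assert a.origin_level is Level.CHRONIC_IV

    def test_chronic_precedence_beats_hospitalization_history(self):
        p = frozenset({"copd"})
        a = self._assign(p, years=(1, 1), adj=50.0)
        assert a.level is Level.CHRONIC_I
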