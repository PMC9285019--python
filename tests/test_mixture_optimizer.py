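import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covermix.data_model import SpeciesParams
from covermix.mixture_optimizer import (
    MixtureCandidate,
    evaluations_to_frame,
    evenness,
    generate_candidates,
    pareto_front,
    seed_cost,
    shortlist,
    simulate_all,
    species_increments,
)
from covermix.polyculture_model import assemble


def make_candidate(levels, increments, registry):
    rec = {sp.code: sp.rec_rate_seeds for sp in registry}
    return MixtureCandidate(
        levels=levels,
        increments=increments,
        densities={c: float(k * increments[c]) for c, k in levels.items()},
        proportions={c: k * increments[c] / rec[c] for c, k in levels.items()},
        n_species=sum(1 for k in levels.values() if k > 0),
    )


class TestGrid:
    def test_default_increments(self, registry):
        assert species_increments(registry) == {"M": 17, "S": 13, "H": 8, "C": 4}

    def test_zero_increment_rejected(self):
        tiny = SpeciesParams("T", "tiny", 1.0, 10.0, 0.9, 1.0)
        with pytest.raises(ValueError, match="zero"):
            species_increments([tiny])

    def test_candidate_count_default_grid(self, registry):
        """The stated enumeration rule (truncated whole-seed increments,
        budget of 120% of recommended rates, 3-4 species) gives 10,432
        candidates; see the methods note on the boundary ambiguity of the
        published 10,418."""
        assert len(generate_candidates(registry)) == 10432

    def test_matches_bruteforce_enumeration_two_species(self):
        reg = [
            SpeciesParams("A", "a", 1.0, 100.0, 0.9, 1.0),
            SpeciesParams("B", "b", 1.0, 60.0, 0.9, 1.0),
        ]
        cands = generate_candidates(reg, 0.1, 1.0, min_species=2, max_species=2)
        inc = species_increments(reg, 0.1, 1.0)
        count = 0
        for ka in range(100 // inc["A"] + 1):
            for kb in range(60 // inc["B"] + 1):
                if ka > 0 and kb > 0 and ka * inc["A"] / 100 + kb * inc["B"] / 60 <= 1.0 + 1e-9:
                    count += 1
        assert len(cands) == count
        for c in cands:
            assert c.densities == {
                s: c.levels[s] * c.increments[s] for s in c.levels
            }

    def test_infeasible_budget_empty(self, registry):
        # three species at one coarse level each already exceed the budget
        assert generate_candidates(registry, 0.4, 1.0, min_species=3) == []


class TestEvenness:
    def test_reference_msh_row(self):
        assert evenness([104.75, 296.05, 61.22]) == pytest.approx(0.81, abs=0.005)

    def test_equal_shares(self):
        assert evenness({"a": 3.3, "b": 3.3, "c": 3.3}) == pytest.approx(1.0)

    def test_single_dominant_species(self):
        assert evenness([1.0, 0.0, 0.0]) == pytest.approx(0.0)

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            evenness([5.0])
        with pytest.raises(ValueError):
            evenness([0.0, 0.0])

    @given(c=st.floats(0.01, 100))
    @settings(deadline=None, max_examples=30)
    def test_scale_invariance(self, c):
        base = [104.75, 296.05, 61.22]
        assert evenness([c * v for v in base]) == pytest.approx(evenness(base))

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.diversity.alpha import pielou_e

        counts = [104.75, 296.05, 61.22]
        assert evenness(counts) == pytest.approx(pielou_e(counts), rel=1e-9)


class TestSeedCost:
    def test_msh_reference_cost(self, registry):
        inc = species_increments(registry)
        cand = make_candidate({"M": 8, "S": 6, "H": 6, "C": 0}, inc, registry)
        assert seed_cost(cand, registry) == pytest.approx(270.95, rel=0.001)

    def test_mhc_reference_cost(self, registry):
        inc = species_increments(registry)
        cand = make_candidate({"M": 1, "S": 0, "H": 2, "C": 4}, inc, registry)
        assert seed_cost(cand, registry) == pytest.approx(136.40, rel=0.001)

    def test_zero_levels_zero_cost(self, registry):
        inc = species_increments(registry)
        cand = make_candidate({c: 0 for c in "MSHC"}, inc, registry)
        assert seed_cost(cand, registry) == 0.0

    def test_linearity(self, registry):
        inc = species_increments(registry)
        one = make_candidate({"M": 4, "S": 3, "H": 3, "C": 0}, inc, registry)
        two = make_candidate({"M": 8, "S": 6, "H": 6, "C": 0}, inc, registry)
        assert seed_cost(two, registry) == pytest.approx(2 * seed_cost(one, registry))


@pytest.fixture(scope="module")
def models(ref_bi):
    return {
        frozenset(s): assemble(s, ref_bi)
        for r in (3, 4)
        for s in combinations("MSHC", r)
    }


class TestSimulateAll:
    def test_reference_row_total(self, registry, models):
        inc = species_increments(registry)
        cand = make_candidate({"M": 8, "S": 6, "H": 6, "C": 0}, inc, registry)
        (ev,) = simulate_all([cand], models, registry)
        assert ev.total_biomass == pytest.approx(462.01, rel=0.005)
        assert ev.evenness == pytest.approx(0.81, abs=0.01)

    def test_total_is_sum_of_parts(self, registry, models):
        rng = np.random.default_rng(5)
        inc = species_increments(registry)
        cands = []
        for _ in range(100):
            levels = {c: int(rng.integers(0, 6)) for c in "MSHC"}
            if sum(1 for v in levels.values() if v > 0) < 3:
                levels["M"], levels["S"], levels["H"] = 1, 1, 1
            cands.append(make_candidate(levels, inc, registry))
        for ev in simulate_all(cands, models, registry):
            assert ev.total_biomass == pytest.approx(sum(ev.biomass.values()), rel=1e-12)

    def test_missing_subset_model(self, registry, models):
        inc = species_increments(registry)
        cand = make_candidate({"M": 1, "S": 1, "H": 0, "C": 0}, inc, registry)
        with pytest.raises(ValueError, match="no polyculture model"):
            simulate_all([cand], models, registry)


def _eval(total, even, cost=0.0):
    cand = MixtureCandidate({}, {}, {}, {}, 0)
    from covermix.mixture_optimizer import MixtureEvaluation

    return MixtureEvaluation(cand, {}, total, even, cost)


class TestParetoFront:
    def test_strict_domination(self):
        evs = [_eval(1, 1), _eval(2, 2)]
        assert pareto_front(evs) == [evs[1]]

    def test_incomparable_points_both_kept(self):
        evs = [_eval(1, 2), _eval(2, 1)]
        assert set(map(id, pareto_front(evs))) == set(map(id, evs))

    def test_duplicates_retained(self):
        evs = [_eval(2, 2), _eval(2, 2), _eval(1, 1)]
        front = pareto_front(evs)
        assert len(front) == 2

    def test_matches_bruteforce_oracle(self):
        """1,000 random points: the front equals an O(n²) dominance scan."""
        rng = np.random.default_rng(123)
        pts = rng.random((1000, 2))
        evs = [_eval(a, b) for a, b in pts]
        front = {id(e) for e in pareto_front(evs)}
        brute = set()
        for i, (ai, bi) in enumerate(pts):
            dominated = any(
                (aj >= ai and bj >= bi) and (aj > ai or bj > bi)
                for j, (aj, bj) in enumerate(pts)
                if j != i
            )
            if not dominated:
                brute.add(id(evs[i]))
        assert front == brute


class TestShortlist:
    def test_reference_shortlist_has_twenty_rows(self, registry, models):
        cands = generate_candidates(registry)
        evals = simulate_all(cands, models, registry)
        front = pareto_front(evals)
        table = shortlist(front, 0.8)
        assert len(table) == 20
        assert table["mixture"].value_counts().to_dict() == {"MSH": 18, "MHC": 2}
        # ordered by decreasing total biomass
        assert (table["total_biomass"].diff().dropna() <= 0).all()
        # every shortlist member is on the front
        fronts = {round(e.total_biomass, 9) for e in front}
        assert set(table["total_biomass"].round(9)) <= fronts

    def test_strict_evenness_floor(self):
        front = [_eval(1, 0.5)]
        assert len(shortlist(front, 0.5)) == 0  # strict >
        assert len(shortlist(front, 0.49)) == 1

    def test_empty_front_rejected(self):
        with pytest.raises(ValueError):
            shortlist([])


def test_evaluations_frame_columns(registry, models):
    inc = species_increments(registry)
    cand = make_candidate({"M": 8, "S": 6, "H": 6, "C": 0}, inc, registry)
    df = evaluations_to_frame(simulate_all([cand], models, registry))
    assert {"level_M", "seeds_M", "prop_M", "biomass_M", "total_biomass",
            "evenness", "cost"} <= set(df.columns)
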