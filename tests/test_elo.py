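import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from retmosaic import (
    ComparisonRecord,
    EloConfig,
    EloState,
    apply_matchup,
    compare_genotypes,
    expected_score,
    gen_comparisons,
    retina_scores,
    run_tournament,
)


def _state(ratings):
    return EloState(ratings=dict(ratings))


class TestExpectedScore:
    def test_equal_ratings_half(self):
        assert expected_score(0.0, 0.0) == 0.5

    def test_one_scale_gap(self):
        assert expected_score(400.0, 0.0, scale=400.0) == pytest.approx(10 / 11)

    @given(st.floats(-2000, 2000), st.floats(-2000, 2000))
    @settings(max_examples=50, deadline=None)
    def test_complement(self, ra, rb):
        assert expected_score(ra, rb) + expected_score(rb, ra) == pytest.approx(1.0)


class TestApplyMatchup:
    def test_equal_ratings_split_k(self):
        s = _state({"a": 0.0, "b": 0.0})
        apply_matchup(s, ComparisonRecord("a", "b", "a"), EloConfig(k_factor=32))
        assert s.ratings["a"] == pytest.approx(16.0)
        assert s.ratings["b"] == pytest.approx(-16.0)

    def test_upset_exchanges_more_points(self):
        cfg = EloConfig(k_factor=32)
        up = _state({"lo": -200.0, "hi": 200.0})
        apply_matchup(up, ComparisonRecord("lo", "hi", "lo"), cfg)
        upset_delta = up.history[-1]["delta"]
        down = _state({"lo": -200.0, "hi": 200.0})
        apply_matchup(down, ComparisonRecord("lo", "hi", "hi"), cfg)
        expected_delta = down.history[-1]["delta"]
        assert upset_delta > cfg.k_factor / 2 > expected_delta

    def test_zero_sum_over_many_matchups(self):
        rng = np.random.default_rng(0)
        ids = [f"i{k}" for k in range(12)]
        s = _state({i: 0.0 for i in ids})
        cfg = EloConfig()
        for _ in range(500):
            a, b = rng.choice(ids, size=2, replace=False)
            w = a if rng.random() < 0.5 else b
            apply_matchup(s, ComparisonRecord(a, b, w), cfg)
            assert s.total == pytest.approx(0.0, abs=1e-9)

    def test_unknown_image_rejected(self):
        with pytest.raises(KeyError):
            apply_matchup(_state({"a": 0.0, "b": 0.0}),
                          ComparisonRecord("a", "zzz", "a"), EloConfig())


class TestRunTournament:
    def test_dominant_image_rating_increases_monotonically(self):
        images = {"champ": {"retina_id": "r1", "genotype": "wt"},
                  "chump": {"retina_id": "r2", "genotype": "mut"}}
        recs = [ComparisonRecord("champ", "chump", "champ")] * 40
        cfg = EloConfig(k_factor=32)
        state = run_tournament(images, recs, cfg)
        gains = [h["post"][0] - h["pre"][0] for h in state.history]
        assert all(0 < g <= cfg.k_factor for g in gains)
        ratings = [h["post"][0] for h in state.history]
        assert ratings == sorted(ratings)

    def test_replay_is_deterministic(self):
        lat = {f"i{k}": float(k) for k in range(10)}
        recs = gen_comparisons(lat, 200, seed=3)
        images = {k: {"retina_id": k, "genotype": "g"} for k in lat}
        s1 = run_tournament(images, recs)
        s2 = run_tournament(images, recs)
        assert s1.ratings == s2.ratings
        assert s1.history == s2.history

    @pytest.mark.parametrize("seed", range(10))
    def test_ratings_recover_latent_scores(self, seed):
        """50 matchups/image sorts 30 images close to their latent quality."""
        lat = {f"i{k}": v for k, v in enumerate(np.linspace(-2, 2, 30))}
        recs = gen_comparisons(lat, 30 * 50, noise_scale=0.5, seed=seed)
        images = {k: {"retina_id": k, "genotype": "g"} for k in lat}
        state = run_tournament(images, recs)
        rho = spearmanr([state.ratings[k] for k in lat], [lat[k] for k in lat]).statistic
        assert rho >= 0.9

    def test_separable_genotypes_converge(self):
        lat = {f"i{k}": (0.0 if k < 10 else 4.0) for k in range(20)}
        images = {k: {"retina_id": k, "genotype": "wt" if lat[k] > 1 else "mut"}
                  for k in lat}

        def chooser(a, b, rng):
            return a if lat[a] >= lat[b] else b

        state = run_tournament(images, chooser, EloConfig(), seed=2)
        assert state.converged
        assert state.rounds_run <= EloConfig().max_rounds

    def test_per_rater_tournaments_agree(self):
        """Independent raters' tournaments give correlated rating vectors."""
        lat = {f"i{k}": v for k, v in enumerate(np.linspace(-2, 2, 20))}
        images = {k: {"retina_id": k, "genotype": "g"} for k in lat}
        recs = gen_comparisons(lat, 3 * 20 * 50, n_raters=3, noise_scale=0.5, seed=4)
        vectors = []
        for rater in ("rater0", "rater1", "rater2"):
            own = [r for r in recs if r.rater == rater]
            state = run_tournament(images, own)
            vectors.append([state.ratings[k] for k in lat])
        for va, vb in itertools.combinations(vectors, 2):
            assert spearmanr(va, vb).statistic >= 0.8


class TestRetinaScores:
    def test_mean_and_singleton(self):
        images = {
            "a1": {"retina_id": "r1", "genotype": "wt"},
            "a2": {"retina_id": "r1", "genotype": "wt"},
            "b1": {"retina_id": "r2", "genotype": "mut"},
        }
        state = _state({"a1": 10.0, "a2": -10.0, "b1": 7.5})
        table = retina_scores(state, images)
        vals = dict(zip(table["retina_id"], table["value"]))
        assert vals == {"r1": 0.0, "r2": 7.5}

    def test_unmapped_image_rejected(self):
        with pytest.raises(KeyError):
            retina_scores(_state({"x": 1.0}), {})

    def test_grand_mean_is_initial_score(self):
        lat = {f"i{k}": float(k % 5) for k in range(16)}
        recs = gen_comparisons(lat, 400, seed=5)
        images = {k: {"retina_id": f"r{j // 2}", "genotype": "g"}
                  for j, k in enumerate(lat)}
        state = run_tournament(images, recs)
        assert np.mean(list(state.ratings.values())) == pytest.approx(0.0, abs=1e-9)


class TestCompareGenotypes:
    @staticmethod
    def _table(groups):
        rows = []
        for g, values in groups.items():
            for i, v in enumerate(values):
                rows.append({"retina_id": f"{g}{i}", "genotype": g,
                             "metric_name": "elo_score", "value": v})
        return pd.DataFrame(rows)

    def test_identical_groups_p_one(self):
        t = self._table({"wt": [1.0, 1.0, 1.0], "mut": [1.0, 1.0, 1.0]})
        out = compare_genotypes(t)
        assert out.loc[0, "p_raw"] == 1.0

    def test_separated_groups_match_exhaustive_permutation(self):
        """Exact rank-sum p for complete separation equals the enumeration
        over all C(12,6) group assignments."""
        a = [1.0, 2, 3, 4, 5, 6]
        b = [10.0, 11, 12, 13, 14, 15]
        out = compare_genotypes(self._table({"a": a, "b": b}))
        # oracle: enumerate every assignment of 6 labels to 12 ranks
        pooled = np.array(a + b)
        observed = sum(
            1 for x in a for y in b if x > y
        )  # Mann-Whitney U of group a
        stats = []
        for combo in itertools.combinations(range(12), 6):
            ga = pooled[list(combo)]
            gb = np.delete(pooled, list(combo))
            stats.append(sum(1 for x in ga for y in gb if x > y))
        stats = np.array(stats)
        dist_to_center = abs(observed - 18)
        p_exact = np.mean(abs(stats - 18) >= dist_to_center)
        assert out.loc[0, "p_raw"] == pytest.approx(p_exact, rel=1e-9)
        assert p_exact == pytest.approx(2 / 924, rel=1e-9)

    def test_bh_adjustment_across_pairs(self):
        rng = np.random.default_rng(8)
        t = self._table({g: list(rng.normal(m, 1, 6))
                         for g, m in [("a", 0), ("b", 0.5), ("c", 3)]})
        out = compare_genotypes(t)
        assert len(out) == 3
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()

    def test_small_genotype_excluded_with_warning(self):
        t = self._table({"a": [1.0, 2, 3], "b": [4.0, 5, 6], "tiny": [1.0]})
        with pytest.warns(UserWarning, match="tiny"):
            out = compare_genotypes(t)
        assert set(out["group_a"]) | set(out["group_b"]) == {"a", "b"}
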