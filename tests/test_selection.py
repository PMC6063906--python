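import numpy as np
import pandas as pd
import pytest

from ceus_radiomics.features import BIOMARKER_CLASSES, FEATURE_NAMES, feature_class
from ceus_radiomics.selection import (RankingConfig, aggregate_rankings,
                                      compute_rankings, concordance_cc,
                                      kruskal_wallis_power,
                                      normalized_dynamic_range, quade_test,
                                      quade_user_independence, select_signature)

import _oracles as oracles


class TestCCC:
    def test_identity_is_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert concordance_cc(x, x) == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        assert concordance_cc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_distinct_constants_are_zero(self):
        assert concordance_cc([2, 2, 2], [5, 5, 5]) == pytest.approx(0.0)

    def test_identical_constants_are_one(self):
        assert concordance_cc([3, 3, 3], [3, 3, 3]) == 1.0

    def test_matches_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, size=8)
            y = 0.5 * x + rng.normal(0, 0.5, size=8)
            assert concordance_cc(x, y) == pytest.approx(
                oracles.ccc_oracle(list(x), list(y)), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            concordance_cc([1, 2], [1, 2, 3])


class TestDynamicRange:
    def test_perfect_repeats_give_one(self):
        assert normalized_dynamic_range([0, 1, 2], [0, 1, 2]) == pytest.approx(1.0)

    def test_anticorrelated_repeats_give_zero(self):
        assert normalized_dynamic_range([0, 1], [1, 0]) == pytest.approx(0.0)

    def test_halving_differences_increases_dr(self, rng):
        test = rng.uniform(0, 10, size=12)
        delta = rng.uniform(-1, 1, size=12)
        # keep the pooled range identical by anchoring min/max values
        test[0], test[1] = 0.0, 10.0
        delta[0] = delta[1] = 0.0
        full = normalized_dynamic_range(test, test + delta)
        half = normalized_dynamic_range(test, test + delta / 2)
        assert half > full

    def test_degenerate_range_is_zero(self):
        assert normalized_dynamic_range([2, 2], [2, 2]) == 0.0


class TestQuade:
    def test_identical_columns_p_one(self):
        data = np.tile(np.arange(6, dtype=float)[:, None], (1, 3))
        assert quade_user_independence(data) == 1.0

    def test_shifted_column_detected(self, rng):
        data = rng.normal(0, 1, size=(10, 3))
        data[:, 2] += 50.0
        assert quade_user_independence(data) < 0.05

    def test_block_permutation_invariance(self, rng):
        data = rng.normal(0, 1, size=(8, 3))
        p1 = quade_user_independence(data)
        p2 = quade_user_independence(data[rng.permutation(8)])
        assert p1 == pytest.approx(p2)

    def test_matches_oracle(self, rng):
        for _ in range(10):
            data = rng.normal(0, 1, size=(6, 3))
            f_got, p_got = quade_test(data)
            f_want, p_want = oracles.quade_oracle(data.tolist())
            assert f_got == pytest.approx(f_want, abs=1e-10)
            assert p_got == pytest.approx(p_want, abs=1e-10)

    def test_matches_published_worked_example(self):
        # classic randomized-block dataset; F and p verified against the
        # base-R quade.test implementation
        y = np.array([[31, 27, 24], [31, 28, 31], [45, 29, 46],
                      [21, 18, 48], [42, 36, 46], [32, 17, 29]], dtype=float)
        f, p = quade_test(y)
        assert f == pytest.approx(5.2833, abs=1e-4)
        assert p == pytest.approx(0.02718, abs=1e-5)


class TestKruskalWallis:
    def test_full_separation_matches_exact_rank_computation(self):
        # three fully separated pairs: H is maximal for n = 6, and the
        # chi-square p follows from the exact rank sums (oracle-computed)
        values = np.array([1, 2, 11, 12, 21, 22], dtype=float)
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        p = kruskal_wallis_power(values, labels)
        h_want, p_want = oracles.kruskal_oracle([[1, 2], [11, 12], [21, 22]])
        assert h_want == pytest.approx(32.0 / 7.0)  # maximal H at this design
        assert p == pytest.approx(p_want, abs=1e-12)
        assert p < 0.11

    def test_label_permutation_invariance(self, rng):
        values = rng.normal(0, 1, size=12)
        labels = np.repeat(["a", "b", "c"], 4)
        perm = rng.permutation(12)
        assert kruskal_wallis_power(values, labels) == pytest.approx(
            kruskal_wallis_power(values[perm], labels[perm]))

    def test_matches_oracle(self, rng):
        for _ in range(10):
            groups = [list(rng.normal(s, 1, size=4)) for s in (0, 0.5, 1)]
            values = np.concatenate(groups)
            labels = np.repeat(["a", "b", "c"], 4)
            h_want, p_want = oracles.kruskal_oracle(groups)
            assert kruskal_wallis_power(values, labels) == pytest.approx(
                p_want, abs=1e-10)

    def test_type_i_error_calibration(self, rng):
        # identically distributed groups reject at ~ the nominal level
        n_sim, alpha = 1000, 0.05
        labels = np.repeat(["a", "b", "c"], 6)
        rejections = sum(
            kruskal_wallis_power(rng.normal(0, 1, size=18), labels) < alpha
            for _ in range(n_sim))
        assert 0.03 <= rejections / n_sim <= 0.07


class TestAggregation:
    def _table(self, ranks):
        df = pd.DataFrame(ranks, columns=["rank_ccc", "rank_dr", "rank_user",
                                          "rank_power"])
        df.index = [f"f{i}" for i in range(len(df))]
        return df

    def test_unanimous_winner(self):
        t = self._table([[1, 1, 1, 1], [2, 3, 2, 2], [3, 2, 3, 3]])
        out = aggregate_rankings(t)
        assert out.loc["f0", "final_rank"] == 1

    def test_tie_broken_by_ccc_rank(self):
        t = self._table([[1, 2, 3, 4], [4, 3, 2, 1]])
        out = aggregate_rankings(t)
        assert out.loc["f0", "final_rank"] == 1  # rank_ccc 1 beats 4

    def test_output_is_permutation(self, rng):
        n = 20
        ranks = np.column_stack([rng.permutation(n) + 1 for _ in range(4)])
        out = aggregate_rankings(self._table(ranks))
        assert sorted(out["final_rank"]) == list(range(1, n + 1))


def engineered_feature_table(seed, n_mice=(5, 5, 4), effect=2.2):
    """Synthetic feature table with one designed 'good' feature per class.

    The designed features are test/retest-stable, observer-insensitive and
    class-discriminative (each via a group-mean pattern, with within-group
    noise keeping their mutual correlation below the pruning threshold).
    Every other feature is noise: unstable between the two acquisitions and
    carrying a systematic per-observer delineation bias.
    """
    rng = np.random.default_rng(seed)
    designed = {"first_order": "fo_median", "textural": "glcm_energy",
                "vascular": "vasc_network_length", "wavelet": "wavD_glrlm_RLN"}
    # four distinct group-mean patterns built from the two orthogonal
    # 3-group contrasts; pairwise pattern correlations stay <= 0.71, and
    # the within-group noise lowers the realized feature correlations
    # further below the 0.75 pruning threshold
    patterns = {"fo_median": (-0.707, 0.0, 0.707),
                "glcm_energy": (0.408, -0.816, 0.408),
                "vasc_network_length": (-0.211, -0.577, 0.789),
                "wavD_glrlm_RLN": (-0.789, 0.577, 0.211)}
    models = [m for m, n in zip(("P1", "P2", "P3"), n_mice) for _ in range(n)]
    users = ("user1", "user2", "user3")
    # systematic observer bias of the noise features
    user_bias = rng.normal(0, 1.0, size=(len(FEATURE_NAMES), len(users)))

    rows = []
    for mi, model in enumerate(models):
        for pos in (1, 2):
            scan_noise = rng.normal(0, 1, size=len(FEATURE_NAMES))
            for ds in (1, 2):
                for ui, user in enumerate(users):
                    row = dict(scan_id=f"m{mi}p{pos}d{ds}", mouse_id=f"m{mi}",
                               model_label=model, position_id=f"p{pos}",
                               user_id=user, dataset=ds)
                    for j, name in enumerate(FEATURE_NAMES):
                        if name in patterns:
                            g = {"P1": 0, "P2": 1, "P3": 2}[model]
                            base = effect * patterns[name][g] + scan_noise[j]
                            row[name] = base + rng.normal(0, 0.05)
                        else:
                            row[name] = rng.normal(0, 1) + user_bias[j, ui]
                    rows.append(row)
    return pd.DataFrame(rows), designed


class TestSelectSignature:
    def test_engineered_features_recovered(self):
        df, designed = engineered_feature_table(seed=0)
        ranking = compute_rankings(df)
        sig = select_signature(ranking, df)
        assert sig.features == designed

    def test_signature_structure_invariants(self):
        df, _ = engineered_feature_table(seed=1)
        ranking = compute_rankings(df)
        sig = select_signature(ranking, df)
        assert len(sig.names) == 4
        assert {feature_class(n) for n in sig.names} == set(BIOMARKER_CLASSES)
        off_diag = sig.correlation.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off_diag) <= 0.75)

    def test_duplicate_feature_forces_replacement(self):
        df, designed = engineered_feature_table(seed=2)
        # make the textural winner a perfect copy of the first-order winner
        df["glcm_energy"] = df["fo_median"]
        ranking = compute_rankings(df)
        sig = select_signature(ranking, df)
        assert sig.features["first_order"] == "fo_median"
        assert sig.features["textural"] != "glcm_energy"

    def test_selection_deterministic(self):
        df, _ = engineered_feature_table(seed=3)
        ranking = compute_rankings(df)
        assert select_signature(ranking, df).features == \
            select_signature(ranking, df).features
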