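import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hostscope as hs
from hostscope.integration import recall_at_fdr, sample_balanced_pairs
from scipy.special import expit


class TestAggregateToGenus:
    def test_max_over_member_genomes(self, tiny_frame):
        scores = pd.DataFrame({"virus_id": ["v", "v"], "genome_id": ["A", "B"],
                               "score": [0.4, 0.9]})
        out = hs.aggregate_to_genus(scores, tiny_frame)
        assert len(out) == 1
        assert out.iloc[0]["score"] == 0.9
        assert out.iloc[0]["genome_id"] == "B"  # contributing genome recorded

    def test_distinct_genera_not_pooled(self, tiny_frame):
        scores = pd.DataFrame({"virus_id": ["v", "v"], "genome_id": ["A", "C"],
                               "score": [0.4, 0.9]})
        out = hs.aggregate_to_genus(scores, tiny_frame)
        assert set(out["host_genus"]) == {"gAB", "gC"}

    def test_empty(self, tiny_frame):
        out = hs.aggregate_to_genus(pd.DataFrame(columns=["virus_id", "genome_id",
                                                          "score"]), tiny_frame)
        assert out.empty


class TestCombinedFeatures:
    def test_best_candidate_rank_one_delta_zero(self):
        sc = {"c1": pd.DataFrame({"virus_id": ["v", "v"], "genome_id": ["A", "B"],
                                  "score": [0.9, 0.6]})}
        out = hs.build_combined_features(sc, ["c1"])
        a = out[out["genome_id"] == "A"].iloc[0]
        b = out[out["genome_id"] == "B"].iloc[0]
        assert (a["c1:score"], a["c1:rank"], a["c1:delta"]) == (0.9, 1.0, 0.0)
        assert (b["c1:score"], b["c1:rank"], b["c1:delta"]) == (0.6, 2.0, pytest.approx(0.3))

    def test_missing_score_imputed(self):
        sc = {"c1": pd.DataFrame({"virus_id": ["v", "v"], "genome_id": ["A", "B"],
                                  "score": [0.9, 0.6]}),
              "c2": pd.DataFrame({"virus_id": ["v"], "genome_id": ["A"],
                                  "score": [0.7]})}
        out = hs.build_combined_features(sc, ["c1", "c2"])
        b = out[out["genome_id"] == "B"].iloc[0]
        assert b["c2:score"] == 0.0
        assert b["c2:rank"] == 2.0  # n_candidates
        assert b["c2:delta"] == pytest.approx(0.7)

    def test_tied_scores_share_min_rank(self):
        sc = {"c1": pd.DataFrame({"virus_id": "v", "genome_id": ["A", "B", "C"],
                                  "score": [0.8, 0.8, 0.2]})}
        out = hs.build_combined_features(sc, ["c1"])
        assert list(out["c1:rank"]) == [1.0, 1.0, 3.0]

    def test_vector_length_is_3k(self):
        sc = {f"c{i}": pd.DataFrame({"virus_id": ["v"], "genome_id": ["A"],
                                     "score": [0.5]}) for i in range(4)}
        out = hs.build_combined_features(sc, sorted(sc))
        assert out.shape[1] == 2 + 3 * 4


class TestCombinedRF:
    def _features(self, n_virus=120, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        labels = []
        for i in range(n_virus):
            v = f"v{i:03d}"
            n_cand = int(rng.integers(2, 20))
            correct = rng.integers(0, n_cand)
            for j in range(n_cand):
                is_corr = int(j == correct) if rng.random() < 0.9 else int(j == (correct + 1) % n_cand)
                s = rng.beta(8, 2) if is_corr else rng.beta(2, 8)
                rows.append((v, f"G{j:02d}", s))
                labels.append(is_corr)
        df = pd.DataFrame(rows, columns=["virus_id", "genome_id", "score"])
        feats = hs.build_combined_features({"c1": df}, ["c1"])
        # rows keep input order within virus groups sorted by genome_id
        lab = (df.sort_values(["virus_id", "genome_id"], kind="mergesort")
                 .reset_index())
        labels = np.array(labels)[lab["index"].to_numpy()]
        return feats, labels

    def test_sampling_caps(self):
        feats, labels = self._features()
        strata = pd.DataFrame({"has_blast": True, "has_crispr": True},
                              index=sorted(set(feats["virus_id"])))
        rows = sample_balanced_pairs(feats, labels, strata, n_per_stratum=50,
                                     max_correct=10, max_incorrect=5, seed=1)
        sub = feats.iloc[rows].assign(label=labels[rows])
        per_virus = sub.groupby("virus_id")["label"].agg(["sum", "count"])
        assert (per_virus["sum"] <= 10).all()
        assert ((per_virus["count"] - per_virus["sum"]) <= 5).all()

    def test_same_seed_same_strata(self):
        feats, labels = self._features()
        strata = pd.DataFrame({"has_blast": True, "has_crispr": False},
                              index=sorted(set(feats["virus_id"])))
        a = sample_balanced_pairs(feats, labels, strata, 30, seed=2)
        b = sample_balanced_pairs(feats, labels, strata, 30, seed=2)
        assert np.array_equal(a, b)

    def test_separable_features_give_high_auc(self):
        from sklearn.metrics import roc_auc_score
        feats, labels = self._features(seed=3)
        strata = pd.DataFrame({"has_blast": True, "has_crispr": True},
                              index=sorted(set(feats["virus_id"])))
        with pytest.warns(UserWarning):
            rf = hs.train_combined_rf(feats, labels, ["c1"], strata,
                                      n_trials=4, seed=4)
        held, held_labels = self._features(n_virus=60, seed=9)
        auc = roc_auc_score(held_labels, rf.score(held))
        assert auc >= 0.9

    def test_single_class_rejected(self):
        feats, labels = self._features()
        strata = pd.DataFrame({"has_blast": True, "has_crispr": True},
                              index=sorted(set(feats["virus_id"])))
        with pytest.raises(ValueError, match="single class"):
            with pytest.warns(UserWarning):
                hs.train_combined_rf(feats, np.ones_like(labels), ["c1"],
                                     strata, n_trials=2, seed=0)

    def test_recall_at_fdr(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        assert recall_at_fdr(y, s, 0.05) == 1.0
        assert recall_at_fdr(1 - y, s, 0.05) == 0.0


class TestCalibration:
    def test_all_correct_curve_is_one(self):
        rng = np.random.default_rng(0)
        c = hs.fit_calibration(rng.uniform(size=500), np.ones(500), window=0.05)
        assert np.allclose(c.ppv, 1.0)

    def test_uninformative_scores_flat_at_base_rate(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(size=5000)
        y = rng.random(5000) < 0.5
        c = hs.fit_calibration(s, y, window=0.05)
        assert np.all(np.abs(c.ppv - 0.5) <= 0.05)

    def test_logistic_generator_recovered(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(size=5000)
        y = rng.random(5000) < expit(4 * (s - 0.5))
        c = hs.fit_calibration(s, y, window=0.05)
        supported = c.support >= 30
        err = np.abs(c.ppv[supported] - expit(4 * (c.grid[supported] - 0.5)))
        assert err.max() <= 0.05

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=25)
    def test_monotone_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 300))
        s = rng.uniform(size=n)
        y = rng.integers(0, 2, n)
        c = hs.fit_calibration(s, y, window=0.05)
        assert (np.diff(c.ppv) >= -1e-12).all()
        assert ((c.ppv >= 0) & (c.ppv <= 1)).all()

    def test_grid_is_0_001(self):
        c = hs.fit_calibration([0.5], [1], window=0.05)
        assert len(c.grid) == 1001
        assert c.grid[1] - c.grid[0] == pytest.approx(0.001)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hs.fit_calibration([], [], window=0.05)

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        c = hs.fit_calibration(rng.uniform(size=100), rng.integers(0, 2, 100))
        p = tmp_path / "c.tsv"
        c.to_tsv(p)
        back = hs.CalibrationCurve.from_tsv(p)
        assert np.allclose(back.ppv, c.ppv)
        assert back.ppv_at(0.5) == pytest.approx(c.ppv_at(0.5))


class TestCompositeScore:
    def test_single_method_identity(self):
        comp, main, used = hs.composite_score({"blast_clf": 0.9})
        assert comp == pytest.approx(0.90)
        assert main == "blast_clf" and used == ["blast_clf"]

    def test_two_methods(self):
        comp, main, used = hs.composite_score({"blast_clf": 0.9, "combined_rf": 0.8})
        assert comp == pytest.approx(1 - 0.1 * (2 * 0.2))  # 0.96
        assert main == "blast_clf"
        assert used == ["blast_clf", "combined_rf"]

    def test_all_below_floor_no_prediction(self):
        comp, main, used = hs.composite_score({"a": 0.45, "b": 0.49})
        assert comp is None and main is None and used == []

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=6))
    @settings(deadline=None)
    def test_formula_and_floor(self, ppvs):
        methods = {f"m{i}": p for i, p in enumerate(ppvs)}
        comp, main, used = hs.composite_score(methods)
        passing = {m: p for m, p in methods.items() if p >= 0.5}
        if not passing:
            assert comp is None
            return
        p_main = max(passing.values())
        expected = 1 - (1 - p_main) * np.prod(
            [2 * (1 - p) for m, p in passing.items()
             if p < p_main or (p == p_main and m != main)])
        assert comp == pytest.approx(expected)
        assert comp >= p_main - 1e-12
        assert comp <= 1 + 1e-12

    @given(st.floats(min_value=0.5, max_value=1),
           st.floats(min_value=0.5, max_value=1, exclude_min=True))
    @settings(deadline=None)
    def test_adding_passing_method_never_decreases(self, p1, p_extra):
        base, _, _ = hs.composite_score({"m1": p1})
        more, _, _ = hs.composite_score({"m1": p1, "m2": p_extra})
        assert more >= base - 1e-12


class TestFinalize:
    def _curve(self):
        # identity-ish calibration: PPV == composite
        grid = np.round(np.arange(0, 1.0005, 0.001), 6)
        return hs.CalibrationCurve(grid=grid, ppv=grid.copy(),
                                   support=np.ones_like(grid), window=0.01)

    def _comps(self):
        return pd.DataFrame({
            "virus_id": ["v1", "v1", "v2", "v3"],
            "host_genus": ["gA", "gB", "gC", "gD"],
            "composite": [0.95, 0.80, 0.89, 0.60],
            "main_method": "blast_clf", "methods_used": "blast_clf",
        })

    def test_report_floor_75(self):
        out = hs.finalize_predictions(self._comps(), self._curve())
        assert set(out["host_genus"]) == {"gA", "gB", "gC"}  # 0.60 -> 60 dropped

    def test_default_min_90_excludes_89(self):
        out = hs.finalize_predictions(self._comps(), self._curve(), min_score=90)
        assert set(out["host_genus"]) == {"gA"}
        assert 89.0 not in out["confidence"].values

    def test_per_virus_ordering(self):
        out = hs.finalize_predictions(self._comps(), self._curve())
        v1 = out[out["virus_id"] == "v1"]
        assert list(v1["host_genus"]) == ["gA", "gB"]
        assert v1["confidence"].is_monotonic_decreasing

    def test_min_score_range_enforced(self):
        with pytest.raises(ValueError):
            hs.finalize_predictions(self._comps(), self._curve(), min_score=60)


class TestIntegrationConfig:
    def test_floor_rescale_invariant(self):
        with pytest.raises(ValueError):
            hs.IntegrationConfig(ppv_floor=0.5, rescale_factor=3.0)
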