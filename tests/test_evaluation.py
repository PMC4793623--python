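import math

import numpy as np
import pytest

from daspfind import (
    DTIDataset,
    LoocvRound,
    ScoreParams,
    alpha_sweep,
    build_graph,
    compute_auc,
    kfold_cv,
    loocv_per_drug,
    loocv_per_interaction,
    rank_after_removing_known,
    remove_interaction,
    score_drug,
)



def identical_twin_dataset():
    """Two drugs with similarity 1.0 sharing one target."""
    return DTIDataset(
        ["d1", "d2"], ["t1", "t2"],
        np.array([[1.0, 0.0], [1.0, 0.0]]),
        np.array([[1.0, 1.0], [1.0, 1.0]]),
        np.eye(2),
    )


class TestLoocvPerInteraction:
    def test_planted_fixture_is_fully_recovered(self, planted_dataset):
        report = loocv_per_interaction(planted_dataset)
        assert report.topk_pct[1] == 100.0
        assert report.auc == 1.0

    def test_one_round_per_interaction(self, fixture_10x8):
        report = loocv_per_interaction(fixture_10x8)
        assert report.n_rounds == fixture_10x8.n_interactions

    def test_topk_monotone(self, fixture_10x8):
        report = loocv_per_interaction(fixture_10x8)
        assert report.topk_pct[1] <= report.topk_pct[2] <= report.topk_pct[5]

    def test_degenerate_single_pair_dataset(self):
        ds = DTIDataset(["d"], ["t"], np.ones((1, 1)), np.ones((1, 1)), np.ones((1, 1)))
        # the only round removes the only edge; one positive, zero negatives
        with pytest.raises(ValueError):
            loocv_per_interaction(ds)

    def test_other_known_targets_stay_in_graph_and_ranking(self):
        # d1 interacts with t1 and t2; when t1 is held out, t2's direct edge
        # remains and outranks it, so the held-out rank reflects competition
        # from known targets.
        ds = DTIDataset(
            ["d1", "d2"], ["t1", "t2", "t3"],
            np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0]]),
            np.array([[1.0, 0.9], [0.9, 1.0]]),
            np.eye(3),
        )
        report = loocv_per_interaction(ds)
        round_t1 = next(
            r for r in report.rounds if r.drug == "d1" and r.removed_targets == ["t1"]
        )
        i_t2 = 1
        assert round_t1.target_scores[i_t2] > round_t1.target_scores[0]
        assert round_t1.test_rank == 2

    def test_engines_agree(self, fixture_10x8):
        a = loocv_per_interaction(fixture_10x8, engine="dfs")
        b = loocv_per_interaction(fixture_10x8, engine="matrix")
        assert a.topk_pct == b.topk_pct
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_patching_equals_full_rebuild(self, fixture_10x8):
        params = ScoreParams()
        report = loocv_per_interaction(fixture_10x8, params)
        hg = build_graph(fixture_10x8, params)
        for r in report.rounds[:5]:
            rebuilt = remove_interaction(hg, r.drug, r.removed_targets[0])
            scores = score_drug(rebuilt, r.drug, params)
            np.testing.assert_allclose(scores, r.target_scores, atol=1e-9)


class TestLoocvPerDrug:
    def test_planted_fixture_is_fully_recovered(self, planted_dataset):
        report = loocv_per_drug(planted_dataset)
        assert report.topk_pct[1] == 100.0

    def test_one_round_per_interacting_drug(self, fixture_10x8):
        report = loocv_per_drug(fixture_10x8)
        n_drugs_with_links = int((fixture_10x8.interactions.sum(axis=1) > 0).sum())
        assert report.n_rounds == n_drugs_with_links

    def test_identical_twins_recover_shared_target(self):
        # removing d1's only link leaves the path d1 - d2 - t1 (weights 1, 1)
        report = loocv_per_drug(identical_twin_dataset())
        assert report.topk_pct[1] == 100.0

    def test_isolated_drug_scores_zero_and_misses(self):
        # no drug-drug similarity edges: after removal nothing is reachable
        ds = DTIDataset(
            ["d1", "d2"], ["t1", "t2"],
            np.array([[1.0, 0.0], [0.0, 1.0]]),
            np.eye(2),
            np.eye(2),
        )
        report = loocv_per_drug(ds)
        assert all((r.target_scores == 0).all() for r in report.rounds)
        assert report.topk_pct[1] == 0.0  # pessimistic ties never count as hits

    def test_modes_coincide_when_each_drug_has_one_link(self):
        rng = np.random.default_rng(7)
        n = 6
        inter = np.zeros((n, n))
        inter[np.arange(n), rng.permutation(n)] = 1.0
        sim = rng.random((n, n))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        ds = DTIDataset(
            [f"D{i}" for i in range(n)], [f"T{i}" for i in range(n)],
            inter, sim, sim.copy(),
        )
        a = loocv_per_interaction(ds)
        b = loocv_per_drug(ds)
        assert a.topk_pct == b.topk_pct


class TestComputeAuc:
    def make_round(self, ds, drug, removed, scores):
        ranks = 1  # rank irrelevant for AUC
        return LoocvRound(drug, removed, np.asarray(scores, dtype=float), ranks)

    def two_target_dataset(self):
        return DTIDataset(
            ["d1"], ["t1", "t2", "t3"],
            np.array([[1.0, 0.0, 0.0]]),
            np.ones((1, 1)),
            np.eye(3),
        )

    def test_perfect_separation_gives_one(self):
        ds = self.two_target_dataset()
        rounds = [self.make_round(ds, "d1", ["t1"], [0.9, 0.1, 0.2])]
        assert compute_auc(rounds, ds) == 1.0

    def test_all_tied_gives_half(self):
        ds = self.two_target_dataset()
        rounds = [self.make_round(ds, "d1", ["t1"], [0.4, 0.4, 0.4])]
        assert compute_auc(rounds, ds) == 0.5

    def test_invariant_under_monotone_transform(self, fixture_10x8):
        report = loocv_per_interaction(fixture_10x8)
        transformed = [
            LoocvRound(r.drug, r.removed_targets,
                       np.log1p(r.target_scores) * 3.0, r.test_rank)
            for r in report.rounds
        ]
        assert compute_auc(transformed, fixture_10x8) == pytest.approx(
            report.auc, abs=1e-12
        )

    def test_no_negatives_is_an_error(self):
        ds = DTIDataset(["d"], ["t"], np.ones((1, 1)), np.ones((1, 1)), np.ones((1, 1)))
        rounds = [self.make_round(ds, "d", ["t"], [1.0])]
        with pytest.raises(ValueError):
            compute_auc(rounds, ds)

    def test_per_round_pooling_switch(self, fixture_10x8):
        report = loocv_per_interaction(fixture_10x8)
        per_round = compute_auc(report.rounds, fixture_10x8, pooling="per-round")
        assert 0.0 <= per_round <= 1.0


class TestRankAfterRemovingKnown:
    def build_round(self, scores):
        return LoocvRound("d1", ["t1"], np.asarray(scores, dtype=float), 1)

    def dataset(self):
        return DTIDataset(
            ["d1"], ["t1", "t2", "t3"],
            np.array([[1.0, 1.0, 0.0]]),
            np.ones((1, 1)),
            np.eye(3),
        )

    def test_known_competitor_excluded(self):
        rank = rank_after_removing_known(self.build_round([0.5, 0.9, 0.1]), self.dataset())
        assert rank == 1

    def test_unknown_competitor_still_counts(self):
        rank = rank_after_removing_known(self.build_round([0.5, 0.9, 0.8]), self.dataset())
        assert rank == 2

    def test_never_worse_than_all_targets_rank(self, fixture_10x8):
        report = loocv_per_interaction(fixture_10x8)
        for r in report.rounds:
            assert rank_after_removing_known(r, fixture_10x8) <= r.test_rank


class TestKfold:
    def test_k_equals_n_reproduces_loocv(self, fixture_10x8):
        n = fixture_10x8.n_interactions
        a = kfold_cv(fixture_10x8, k=n, seed=1)
        b = loocv_per_interaction(fixture_10x8)
        assert a.topk_pct == b.topk_pct
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_fixed_seed_is_deterministic(self, fixture_10x8):
        a = kfold_cv(fixture_10x8, k=5, seed=42)
        b = kfold_cv(fixture_10x8, k=5, seed=42)
        assert a.topk_pct == b.topk_pct and a.auc == b.auc

    def test_seed_stability(self):
        # removing small folds en bloc perturbs each round only slightly, so
        # any seed's top-1 stays within sampling noise of the LOOCV value
        from daspfind import FixtureSpec, generate_dataset

        ds = generate_dataset(FixtureSpec(n_drugs=20, n_targets=16, n_clusters=4, seed=5))
        loocv_top1 = loocv_per_interaction(ds).topk_pct[1]
        for seed in (0, 1, 2):
            kfold_top1 = kfold_cv(ds, k=10, seed=seed).topk_pct[1]
            assert abs(kfold_top1 - loocv_top1) <= 15.0

    def test_k_larger_than_interactions_rejected(self, fixture_10x8):
        with pytest.raises(ValueError):
            kfold_cv(fixture_10x8, k=10_000)


class TestAlphaSweep:
    def test_singleton_matches_loocv(self, fixture_10x8):
        table = alpha_sweep(fixture_10x8, [2.26])
        assert table == [(2.26, loocv_per_interaction(fixture_10x8).topk_pct[1])]

    def test_unit_weights_make_top1_alpha_invariant(self, planted_dataset):
        table = alpha_sweep(planted_dataset, [0.5, 2.26, 5.0])
        top1 = {t1 for _, t1 in table}
        assert top1 == {100.0}

    def test_ranking_flips_at_computable_alpha(self):
        # drug d0: one length-2 path to tA with product a, and two
        # length-3 paths to tB with product b each.  Scores cross where
        # a**(2*alpha) = 2 * b**(3*alpha), i.e.
        # alpha* = ln 2 / (2 ln a - 3 ln b).
        a, b = 0.9, 0.8
        drug_sim = np.eye(6)
        for i, j, w in [(0, 1, a), (0, 2, 1.0), (2, 3, b), (0, 4, 1.0), (4, 5, b)]:
            drug_sim[i, j] = drug_sim[j, i] = w
        inter = np.zeros((6, 2))
        inter[1, 0] = 1.0  # d1 - tA
        inter[3, 1] = 1.0  # d3 - tB
        inter[5, 1] = 1.0  # d5 - tB
        ds = DTIDataset(
            [f"d{i}" for i in range(6)], ["tA", "tB"],
            inter, drug_sim, np.eye(2),
        )
        hg = build_graph(ds, ScoreParams(sim_cutoff=0.0))
        alpha_star = math.log(2) / (2 * math.log(a) - 3 * math.log(b))
        for alpha, winner in [(alpha_star - 0.4, "tB"), (alpha_star + 0.4, "tA")]:
            p = ScoreParams(alpha=alpha, sim_cutoff=0.0)
            scores = score_drug(hg, "d0", p)
            best = ds.target_ids[int(np.argmax(scores))]
            assert best == winner
        # at the crossing itself the two scores are equal
        p = ScoreParams(alpha=alpha_star, sim_cutoff=0.0)
        s = score_drug(hg, "d0", p)
        assert s[0] == pytest.approx(s[1], rel=1e-9)

    def test_empty_alpha_list_rejected(self, fixture_10x8):
        with pytest.raises(ValueError):
            alpha_sweep(fixture_10x8, [])


class TestReportOutput:
    def test_keyvalue_file(self, fixture_10x8, tmp_path):
        report = loocv_per_interaction(fixture_10x8)
        out = tmp_path / "report.tsv"
        report.write(out)
        kv = dict(
            line.split("\t") for line in out.read_text().splitlines()
        )
        assert kv["mode"] == "per-interaction"
        assert float(kv["top1"]) == report.topk_pct[1]
        assert float(kv["auc"]) == pytest.approx(100 * report.auc, abs=0.005)
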