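"""Ranking, panel construction and retrieval-effectiveness metrics."""
import numpy as np
import pytest

import pitchshapes as ps
from pitchshapes.descriptors import FeatureVector
from pitchshapes.errors import DataError
from pitchshapes.retrieval import (
    DescriptorRetrieval,
    RankedList,
    RelevanceJudgments,
    interpolated_pr,
)


def make_ranking(ids, distances=None, query="q", name="MFC"):
    if distances is None:
        distances = np.arange(len(ids), dtype=float)
    return RankedList(query_id=query, descriptor_name=name, image_ids=tuple(ids), distances=np.asarray(distances, float))


class TestL2Distance:
    def test_three_four_five(self):
        a = FeatureVector("AllD", [0, 0, 0, 0, 0])
        b = FeatureVector("AllD", [3, 4, 0, 0, 0])
        assert ps.l2_distance(a, b) == 5.0
        assert ps.l2_distance(a, a) == 0.0
        assert ps.l2_distance(b, a) == 5.0

    def test_descriptor_mismatch_rejected(self):
        with pytest.raises(DataError):
            ps.l2_distance(FeatureVector("MF", [1.0]), FeatureVector("FA", [1.0]))


class TestRankCollection:
    def test_identical_item_ranks_first_at_zero(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 5.0]])
        est = DescriptorRetrieval(exclude_query=False).fit(X, ["a", "b", "c"])
        ranking = est.rank(FeatureVector("MFC", [1.0, 1.0], image_id="other"))
        assert ranking.image_ids[0] == "b" and ranking.distances[0] == 0.0

    def test_query_excluded_from_own_ranking(self, small_table):
        qid = small_table["image_id"].iloc[0]
        ranking = ps.rank_collection(ps.feature_vector(small_table, qid, "MFC"), small_table)
        assert qid not in ranking.image_ids
        assert len(ranking.image_ids) == len(small_table) - 1

    def test_order_matches_full_sort_oracle(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(200, 8))
        ids = [f"i{k:03d}" for k in range(200)]
        q = FeatureVector("MFC", rng.normal(size=8), image_id="query")
        ranking = DescriptorRetrieval(exclude_query=False).fit(X, ids).rank(q)
        d = np.linalg.norm(X - q.values, axis=1)
        oracle = [ids[k] for k in sorted(range(200), key=lambda k: (d[k], ids[k]))]
        assert list(ranking.image_ids) == oracle
        assert (np.diff(ranking.distances) >= 0).all()

    def test_distance_ties_broken_by_id(self):
        X = np.array([[1.0], [1.0], [0.5]])
        ranking = DescriptorRetrieval(exclude_query=False).fit(X, ["z", "a", "m"]).rank(
            FeatureVector("MF", [0.0], image_id="q")
        )
        assert list(ranking.image_ids) == ["m", "a", "z"]

    def test_ranking_invariant_under_monotone_distance_transform(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(50, 4))
        ids = [f"i{k}" for k in range(50)]
        q = FeatureVector("MFC", rng.normal(size=4), image_id="q")
        base = DescriptorRetrieval(exclude_query=False).fit(X, ids).rank(q)
        squared = DescriptorRetrieval(exclude_query=False).fit(X * 3.0, ids).rank(
            FeatureVector("MFC", q.values * 3.0, image_id="q")
        )
        assert base.image_ids == squared.image_ids


class TestBuildPanel:
    def _disjoint_rankings(self, n_desc=7, top=12):
        out = {}
        for d in range(n_desc):
            ids = [f"d{d}_img{k}" for k in range(top + 3)]
            out[f"desc{d}"] = make_ranking(ids, name="MFC")
        return out

    def test_disjoint_top12_gives_84(self):
        panel = ps.build_panel(self._disjoint_rankings(), top_n=12, seed=0)
        assert len(panel) == 84

    def test_identical_rankings_collapse_to_12(self):
        one = make_ranking([f"img{k}" for k in range(15)])
        panel = ps.build_panel({f"d{i}": one for i in range(7)}, top_n=12, seed=0)
        assert len(panel) == 12

    def test_seed_reproducibility_and_permutation(self):
        rankings = self._disjoint_rankings()
        p1 = ps.build_panel(rankings, seed=5)
        p2 = ps.build_panel(rankings, seed=5)
        p3 = ps.build_panel(rankings, seed=6)
        assert p1 == p2
        assert set(p1) == set(p3) and p1 != p3

    def test_short_ranking_rejected(self):
        with pytest.raises(DataError):
            ps.build_panel({"d": make_ranking(["a", "b"])}, top_n=12, seed=0)


class TestPrecisionRecall:
    def test_precision_examples(self):
        ranking = make_ranking(list("abcdefghij"))
        assert ps.precision_at(ranking, set("abcde"), 5) == 1.0
        assert ps.precision_at(ranking, {"a", "c"}, 5) == pytest.approx(0.4)
        assert ps.precision_at(ranking, {"x"}, 5) == 0.0

    def test_recall_examples(self):
        ranking = make_ranking([f"i{k}" for k in range(20)])
        relevant = {f"i{k}" for k in range(4)} | {f"x{k}" for k in range(6)}  # rt = 10
        assert ps.recall_at(ranking, relevant, 10) == pytest.approx(0.4)
        full = set(ranking.image_ids)
        assert ps.recall_at(ranking, full, 20) == 1.0

    def test_empty_relevant_set_rejected(self):
        ranking = make_ranking(list("abc"))
        with pytest.raises(DataError):
            ps.recall_at(ranking, set(), 2)
        with pytest.raises(DataError):
            ps.pr_curve(ranking, set())

    def test_recall_monotone_in_n(self):
        rng = np.random.default_rng(2)
        ids = [f"i{k}" for k in range(30)]
        ranking = make_ranking(ids)
        relevant = set(rng.choice(ids, size=8, replace=False))
        values = [ps.recall_at(ranking, relevant, n) for n in range(1, 31)]
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_counts_are_integers(self):
        ranking = make_ranking([f"i{k}" for k in range(12)])
        relevant = {"i0", "i3", "i7"}
        for n in (5, 10):
            p = ps.precision_at(ranking, relevant, n)
            r = ps.recall_at(ranking, relevant, n)
            assert (p * n) == pytest.approx(round(p * n))
            assert (r * len(relevant)) == pytest.approx(round(r * len(relevant)))


class TestPrCurve:
    def test_perfect_ranking_constant_precision(self):
        ranking = make_ranking(list("abcde"))
        pts = ps.pr_curve(ranking, {"a", "b"})
        assert (pts[:, 1] == 1.0).all()
        interp = interpolated_pr(pts)
        assert (interp[:, 1] == 1.0).all()

    def test_single_relevant_at_rank_one(self):
        ranking = make_ranking([f"i{k}" for k in range(10)])
        pts = ps.pr_curve(ranking, {"i0"})
        assert pts.tolist() == [[1.0, 1.0]]

    def test_random_ranking_precision_near_base_rate(self):
        rng = np.random.default_rng(9)
        ids = [f"i{k}" for k in range(400)]
        relevant = set(rng.choice(ids, size=100, replace=False))
        perm = list(rng.permutation(ids))
        pts = ps.pr_curve(make_ranking(perm), relevant)
        assert pts[:, 1].mean() == pytest.approx(0.25, abs=0.07)


class TestEffectivenessReport:
    def test_hand_computed_single_cell(self):
        ranking = make_ranking([f"i{k}" for k in range(12)])
        j = RelevanceJudgments(
            query_id="q", rater_id="A",
            relevant=frozenset({"i0", "i2", "i7", "i11"}),
            panel=tuple(f"i{k}" for k in range(12)),
        )
        report = ps.effectiveness_report({"q": {"MFC": ranking}}, [j], descriptors=("MFC",))
        row = report.cells.iloc[0]
        assert row["P@5"] == pytest.approx(2 / 5)
        assert row["P@10"] == pytest.approx(3 / 10)
        assert row["R@5"] == pytest.approx(2 / 4)
        assert row["R@10"] == pytest.approx(3 / 4)

    def test_all_relevant_gives_unit_precision(self):
        ids = [f"i{k}" for k in range(12)]
        rankings = {"q": {d: make_ranking(ids, name="MFC") for d in ("MFC", "MF")}}
        j = RelevanceJudgments("q", "A", frozenset(ids), tuple(ids))
        report = ps.effectiveness_report(rankings, [j], descriptors=("MFC", "MF"))
        assert (report.cells["P@5"] == 1.0).all()
        assert (report.cells["P@10"] == 1.0).all()

    def test_missing_cells_listed_not_fatal(self):
        ids = [f"i{k}" for k in range(12)]
        rankings = {"q1": {"MFC": make_ranking(ids)}}
        js = [
            RelevanceJudgments("q1", "A", frozenset({"i0"}), tuple(ids)),
            RelevanceJudgments("q2", "A", frozenset({"i0"}), tuple(ids)),
        ]
        report = ps.effectiveness_report(rankings, js, descriptors=("MFC",))
        assert ("MFC", "q2") in report.missing
        assert len(report.cells) == 1


class TestJudgmentsIO:
    def test_csv_roundtrip(self, tmp_path):
        import pandas as pd

        rows = []
        for k in range(6):
            rows.append({"query_id": "q1", "rater_id": "A", "image_id": f"i{k}",
                         "shown": 1, "relevant": int(k < 2)})
        rows.append({"query_id": "q1", "rater_id": "A", "image_id": "hidden",
                     "shown": 0, "relevant": 0})
        path = tmp_path / "j.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        judged = ps.load_judgments(path)
        assert len(judged) == 1
        assert judged[0].relevant == {"i0", "i1"}
        assert "hidden" not in judged[0].panel
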