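"""Content-based image retrieval over descriptor tables, and its
effectiveness evaluation.

A query image's feature vector is compared to every collection image by
Euclidean (L2) distance and the collection ranked from most to least
similar. Rater relevance judgments on panels built from the top of these
rankings then yield precision and recall at cut-offs:

    P@n = r / n        R@n = r / rt

with ``r`` the relevant images among the top n and ``rt`` the total
relevant for the query. The evaluation panel shown to a rater is the union
of each descriptor's top-12, deduplicated and seed-shuffled (seven
descriptors with disjoint top-12 lists give an 84-image panel).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from sklearn.base import BaseEstimator

from .descriptors import DESCRIPTOR_NAMES, FeatureVector, descriptor_matrix, feature_vector
from .errors import DataError

DEFAULT_TOP_N = 12
#: Standard recall levels for the interpolated precision x recall curve.
RECALL_LEVELS = np.linspace(0.0, 1.0, 11)


@dataclass(frozen=True)
class RankedList:
    """A collection ranked by ascending distance to one query."""

    query_id: str
    descriptor_name: str
    image_ids: tuple[str, ...]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "distances", d)
        if len(self.image_ids) != len(d):
            raise DataError("ids and distances must have equal length")
        if len(set(self.image_ids)) != len(self.image_ids):
            raise DataError("ranked list contains duplicate image ids")
        if np.any(np.diff(d) < 0):
            raise DataError("distances must be non-decreasing")

    def top(self, n: int) -> tuple[str, ...]:
        if n > len(self.image_ids):
            raise DataError(f"ranking has only {len(self.image_ids)} entries, need {n}")
        return self.image_ids[:n]


@dataclass(frozen=True)
class RelevanceJudgments:
    """One rater's binary judgments on one query's panel."""

    query_id: str
    rater_id: str
    relevant: frozenset[str]
    panel: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "relevant", frozenset(self.relevant))
        if not self.relevant <= set(self.panel):
            raise DataError("relevant ids must be a subset of the shown panel")


def l2_distance(a: FeatureVector, b: FeatureVector) -> float:
    """Euclidean distance between two same-descriptor feature vectors."""
    if a.descriptor_name != b.descriptor_name:
        raise DataError(
            f"descriptor mismatch: {a.descriptor_name} vs {b.descriptor_name}"
        )
    if len(a.values) != len(b.values):
        raise DataError("feature-vector length mismatch")
    return float(np.linalg.norm(a.values - b.values))


class DescriptorRetrieval(BaseEstimator):
    """L2 nearest-neighbour ranking over a fitted collection.

    sklearn-style estimator: ``fit`` stores the collection's feature
    matrix and ids, ``rank`` returns the full ascending-distance ordering
    for a query vector. Ties in distance are broken by image id ascending
    so rankings are reproducible.

    Parameters
    ----------
    exclude_query : bool, default True
        Drop the query's own id from its ranking; a self-match at
        distance 0 carries no information and would inflate P@n.
    """

    def __init__(self, exclude_query: bool = True):
        self.exclude_query = exclude_query

    def fit(self, X: np.ndarray, image_ids: Sequence[str]):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) == 0:
            raise DataError("collection must be a nonempty 2D array")
        if len(image_ids) != len(X):
            raise DataError("image_ids must match the collection rows")
        self.X_ = X
        self.image_ids_ = np.asarray([str(i) for i in image_ids], dtype=object)
        return self

    def rank(self, query: FeatureVector) -> RankedList:
        if query.values.shape[0] != self.X_.shape[1]:
            raise DataError("query length does not match the fitted collection")
        dist = np.linalg.norm(self.X_ - query.values[None, :], axis=1)
        keep = np.ones(len(dist), dtype=bool)
        if self.exclude_query and query.image_id:
            keep = self.image_ids_ != query.image_id
        ids, dist = self.image_ids_[keep], dist[keep]
        order = np.lexsort((ids, dist))
        return RankedList(
            query_id=query.image_id,
            descriptor_name=query.descriptor_name,
            image_ids=tuple(ids[order]),
            distances=dist[order],
        )


def rank_collection(
    query: FeatureVector,
    table: pd.DataFrame,
    exclude_query: bool = True,
) -> RankedList:
    """Rank a descriptor table's images by L2 distance to a query."""
    ids, X = descriptor_matrix(table, query.descriptor_name)
    return DescriptorRetrieval(exclude_query=exclude_query).fit(X, ids).rank(query)


def rank_all(
    query_id: str,
    table: pd.DataFrame,
    descriptors: Sequence[str] = DESCRIPTOR_NAMES,
    exclude_query: bool = True,
) -> dict[str, RankedList]:
    """One RankedList per descriptor for a query drawn from the table."""
    return {
        name: rank_collection(feature_vector(table, query_id, name), table, exclude_query)
        for name in descriptors
    }


def build_panel(
    rankings: Mapping[str, RankedList],
    top_n: int = DEFAULT_TOP_N,
    seed: int = 0,
) -> tuple[str, ...]:
    """Evaluation panel: union of each descriptor's top-``top_n``,
    deduplicated, shuffled with the given seed.

    With 7 pairwise-disjoint top-12 lists the panel has 84 images; the
    same seed reproduces the same order, different seeds permute the same
    set.
    """
    seen: dict[str, None] = {}
    for ranking in rankings.values():
        for image_id in ranking.top(top_n):
            seen.setdefault(image_id, None)
    panel = list(seen)
    rng = np.random.default_rng(seed)
    return tuple(panel[i] for i in rng.permutation(len(panel)))


def precision_at(ranking: RankedList, judged_relevant: set[str], n: int) -> float:
    """P@n = |top-n ∩ relevant| / n."""
    if n < 1:
        raise DataError("n must be >= 1")
    top = ranking.top(n)
    return sum(1 for i in top if i in judged_relevant) / n


def recall_at(ranking: RankedList, judged_relevant: set[str], n: int) -> float:
    """R@n = |top-n ∩ relevant| / |relevant|."""
    if not judged_relevant:
        raise DataError("recall undefined: no judged-relevant images")
    top = ranking.top(n)
    return sum(1 for i in top if i in judged_relevant) / len(judged_relevant)


def pr_curve(ranking: RankedList, judged_relevant: set[str]) -> np.ndarray:
    """(recall, precision) at each rank where a relevant image appears."""
    if not judged_relevant:
        raise DataError("recall undefined: no judged-relevant images")
    points = []
    hits = 0
    for k, image_id in enumerate(ranking.image_ids, start=1):
        if image_id in judged_relevant:
            hits += 1
            points.append((hits / len(judged_relevant), hits / k))
    return np.asarray(points, dtype=float).reshape(-1, 2)


def interpolated_pr(points: np.ndarray, levels: np.ndarray = RECALL_LEVELS) -> np.ndarray:
    """11-point interpolated precision: at each recall level, the maximum
    precision among points with recall >= that level (0 if none)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    out = np.zeros((len(levels), 2))
    out[:, 0] = levels
    for i, level in enumerate(levels):
        ok = pts[:, 0] >= level - 1e-12
        out[i, 1] = pts[ok, 1].max() if ok.any() else 0.0
    return out


@dataclass
class EffectivenessReport:
    """Per-cell retrieval metrics and their per-descriptor aggregation.

    ``cells`` has one row per (descriptor, query, rater) with P@5, P@10,
    R@5, R@10; ``summary`` gives mean and sd per descriptor across cells;
    ``pr_curves`` maps descriptor -> mean 11-point interpolated
    precision x recall curve; ``missing`` lists (descriptor, query) pairs
    with no ranking or no judgments.
    """

    cells: pd.DataFrame
    summary: pd.DataFrame
    pr_curves: dict[str, np.ndarray] = field(default_factory=dict)
    missing: list[tuple[str, str]] = field(default_factory=list)


def effectiveness_report(
    rankings: Mapping[str, Mapping[str, RankedList]],
    judgments: Iterable[RelevanceJudgments],
    descriptors: Sequence[str] = DESCRIPTOR_NAMES,
) -> EffectivenessReport:
    """Evaluate every descriptor against every rater's judgments.

    ``rankings`` maps query_id -> descriptor -> RankedList. For each cell
    the judged-relevant set is the rater's selections; images never shown
    to the rater do not enter rt. Missing cells are reported, not fatal.
    """
    judgment_list = list(judgments)
    rows = []
    missing: list[tuple[str, str]] = []
    raw_curves: dict[str, list[np.ndarray]] = {d: [] for d in descriptors}
    for j in judgment_list:
        per_query = rankings.get(j.query_id)
        for name in descriptors:
            ranking = per_query.get(name) if per_query else None
            if ranking is None:
                missing.append((name, j.query_id))
                continue
            if not j.relevant:
                missing.append((name, j.query_id))
                continue
            rows.append(
                {
                    "descriptor": name,
                    "query_id": j.query_id,
                    "rater_id": j.rater_id,
                    "P@5": precision_at(ranking, j.relevant, 5),
                    "P@10": precision_at(ranking, j.relevant, 10),
                    "R@5": recall_at(ranking, j.relevant, 5),
                    "R@10": recall_at(ranking, j.relevant, 10),
                }
            )
            raw_curves[name].append(interpolated_pr(pr_curve(ranking, j.relevant)))
    if not rows:
        raise DataError("no (descriptor, query, rater) cells could be evaluated")
    cells = pd.DataFrame(rows)
    summary = (
        cells.groupby("descriptor")[["P@5", "P@10", "R@5", "R@10"]]
        .agg(["mean", "std"])
        .reindex([d for d in descriptors if d in cells["descriptor"].values])
    )
    pr_curves = {
        name: np.mean(np.stack(curves), axis=0)
        for name, curves in raw_curves.items()
        if curves
    }
    return EffectivenessReport(cells=cells, summary=summary, pr_curves=pr_curves, missing=missing)


def load_judgments(path) -> list[RelevanceJudgments]:
    """Read judgments from CSV {query_id, rater_id, image_id, shown, relevant}."""
    df = pd.read_csv(path, dtype={"query_id": str, "rater_id": str, "image_id": str})
    required = {"query_id", "rater_id", "image_id", "shown", "relevant"}
    if not required <= set(df.columns):
        raise DataError(f"judgments file must have columns {sorted(required)}")
    out = []
    for (q, r), grp in df.groupby(["query_id", "rater_id"], sort=True):
        shown = grp.loc[grp["shown"].astype(bool), "image_id"]
        rel = grp.loc[grp["shown"].astype(bool) & grp["relevant"].astype(bool), "image_id"]
        out.append(
            RelevanceJudgments(
                query_id=q, rater_id=r, relevant=frozenset(rel), panel=tuple(shown)
            )
        )
    if not out:
        raise DataError("no judgments found")
    return out
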