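"""Inter-rater agreement on relevance judgments.

Cohen's kappa corrects observed agreement for the agreement expected from
the raters' marginal label frequencies:

    kappa = (p_o - p_e) / (1 - p_e)

Interpretation bands: kappa <= 0.2 slight; 0.2-0.4 fair; 0.4-0.6
moderate; 0.6-0.8 substantial; > 0.8 almost perfect. Alongside kappa, the
raw percentages of items both raters judged non-relevant (NR-NR) or both
relevant (R-R) are reported; kappa is conventionally also printed x100
next to these percentages.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .retrieval import RelevanceJudgments

#: (upper bound, label) for each kappa interpretation band.
KAPPA_BANDS = (
    (0.2, "Slight"),
    (0.4, "Fair"),
    (0.6, "Moderate"),
    (0.8, "Substantial"),
    (1.0, "Almost perfect"),
)


def _as_binary(labels: Sequence[int]) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.ndim != 1 or len(arr) == 0:
        raise DataError("labels must be a nonempty 1D sequence")
    return arr.astype(bool).astype(int)


def cohen_kappa(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Cohen's kappa for two binary label sequences.

    Degenerate case: if both raters give the same constant label to every
    item, expected agreement p_e is 1 and the formula is 0/0; agreement is
    nevertheless perfect, so kappa is defined as 1 (with a warning). For
    binary labels p_e = 1 occurs only in that identical-constant case, so
    the p_e = 1-with-disagreement error path cannot trigger on valid
    input; it is kept as a guard.
    """
    a, b = _as_binary(labels_a), _as_binary(labels_b)
    if len(a) != len(b):
        raise DataError("label sequences must have equal length")
    n = len(a)
    p_o = float(np.mean(a == b))
    p_e = float(np.mean(a) * np.mean(b) + (1 - np.mean(a)) * (1 - np.mean(b)))
    if p_e >= 1.0 - 1e-15:
        if p_o == 1.0:
            warnings.warn(
                "both raters are constant and identical; kappa defined as 1",
                stacklevel=2,
            )
            return 1.0
        raise DataError("kappa undefined: expected agreement 1 with disagreement")
    return (p_o - p_e) / (1.0 - p_e)


def agreement_band(kappa: float) -> str:
    """Interpretation label for a kappa value in [-1, 1]."""
    if not -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12:
        raise DataError(f"kappa {kappa} outside [-1, 1]")
    for upper, label in KAPPA_BANDS:
        if kappa <= upper + 1e-12:
            return label
    return KAPPA_BANDS[-1][1]  # pragma: no cover


def percent_agreement(labels_a: Sequence[int], labels_b: Sequence[int]) -> tuple[float, float]:
    """(NR-NR %, R-R %): share of items both judged non-relevant and both
    judged relevant, as percentages of all items."""
    a, b = _as_binary(labels_a), _as_binary(labels_b)
    if len(a) != len(b):
        raise DataError("label sequences must have equal length")
    n = len(a)
    both_nr = int(np.sum((a == 0) & (b == 0)))
    both_r = int(np.sum((a == 1) & (b == 1)))
    return 100.0 * both_nr / n, 100.0 * both_r / n


@dataclass(frozen=True)
class AgreementReport:
    """Pairwise agreement for one rater pair on one query's panel."""

    query_id: str
    rater_a: str
    rater_b: str
    kappa: float
    band: str
    pct_nr_nr: float
    pct_r_r: float


def _panel_labels(j: RelevanceJudgments, items: Sequence[str]) -> np.ndarray:
    return np.array([1 if i in j.relevant else 0 for i in items], dtype=int)


def pairwise_agreement(
    judgments: Iterable[RelevanceJudgments],
    descriptor_panels: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
) -> pd.DataFrame:
    """Pairwise kappa and percent agreement per query, optionally
    restricted to per-descriptor retrieved sets.

    All raters of a query must have judged the same panel. Without
    ``descriptor_panels`` the items are the full shared panel (descriptor
    "all"); with it (descriptor -> query_id -> retrieved ids), one row per
    descriptor restricts the items to that descriptor's contribution.

    Returns a tidy frame with columns query_id, descriptor, pair, kappa,
    kappa_x100, band, pct_nr_nr, pct_r_r.
    """
    by_query: dict[str, list[RelevanceJudgments]] = {}
    for j in judgments:
        by_query.setdefault(j.query_id, []).append(j)
    rows = []
    for query_id, raters in sorted(by_query.items()):
        if len(raters) < 2:
            continue
        panels = {frozenset(j.panel) for j in raters}
        if len(panels) != 1:
            raise DataError(f"raters of query {query_id!r} saw different panels")
        shared_panel = sorted(raters[0].panel)
        item_sets: dict[str, Sequence[str]] = {"all": shared_panel}
        if descriptor_panels is not None:
            for name, per_query in descriptor_panels.items():
                retrieved = per_query.get(query_id)
                if retrieved is not None:
                    item_sets[name] = [i for i in shared_panel if i in set(retrieved)]
        for j_a, j_b in itertools.combinations(sorted(raters, key=lambda j: j.rater_id), 2):
            for name, items in item_sets.items():
                if not items:
                    continue
                a = _panel_labels(j_a, items)
                b = _panel_labels(j_b, items)
                kappa = cohen_kappa(a, b)
                nr_nr, r_r = percent_agreement(a, b)
                rows.append(
                    {
                        "query_id": query_id,
                        "descriptor": name,
                        "pair": f"{j_a.rater_id} x {j_b.rater_id}",
                        "kappa": kappa,
                        "kappa_x100": 100.0 * kappa,
                        "band": agreement_band(kappa),
                        "pct_nr_nr": nr_nr,
                        "pct_r_r": r_r,
                    }
                )
    if not rows:
        raise DataError("no rater pairs to compare")
    return pd.DataFrame(rows)
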