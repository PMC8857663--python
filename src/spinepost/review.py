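"""Blinded subjective-review protocol for contour quality.

For each vertebral level a fixed number of slices with a human delineation
and a fixed number with an automatic delineation are drawn from pools,
shuffled into a single seeded presentation order, and shown without source
attribution.  Raters answer two questions per item: who drew the contour
(human or computer), and a quality rating on a 4-point scale —
1 large, obvious errors; 2 minor errors that must be corrected for
high-precision radiotherapy; 3 minor, clinically not significant errors;
4 precise.  Clinical acceptability is defined as a rating of 3 or 4.
The analysis compares sources on identification accuracy and on the rating
distribution with chi-squared tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import LEVEL_NAMES

__all__ = ["ReviewSession", "build_review_session", "analyze_review",
           "RATING_SCALE", "ACCEPTABLE_RATINGS"]

SOURCES = ("human", "automatic")
RATING_SCALE = (1, 2, 3, 4)
ACCEPTABLE_RATINGS = (3, 4)


@dataclass
class ReviewSession:
    """A blinded review: presented items plus a separately stored blinding map.

    ``presented`` lists items in presentation order (``item_id``,
    ``level_name``, ``slice_ref``) without source information; ``blinding``
    maps item_id → true source and is only consulted at analysis time.
    """

    presented: pd.DataFrame
    blinding: dict[int, str]
    seed: int
    responses: dict[int, tuple[str, int]] = field(default_factory=dict)

    def respond(self, item_id: int, guessed_source: str, rating: int) -> None:
        if guessed_source not in SOURCES:
            raise ValueError(f"guess must be one of {SOURCES}")
        if rating not in RATING_SCALE:
            raise ValueError(f"rating must be one of {RATING_SCALE}")
        if item_id not in self.blinding:
            raise KeyError(f"unknown item {item_id}")
        self.responses[item_id] = (guessed_source, rating)

    def presented_json(self) -> str:
        return json.dumps(self.presented.to_dict(orient="records"), indent=2)

    def blinding_json(self) -> str:
        return json.dumps({str(k): v for k, v in self.blinding.items()}, indent=2)


def build_review_session(
    human_pool: dict[str, list],
    auto_pool: dict[str, list],
    per_level_human: int = 3,
    per_level_auto: int = 3,
    seed: int = 0,
    levels: tuple[str, ...] = LEVEL_NAMES,
) -> ReviewSession:
    """Draw a blinded session: per level, fixed counts from each source pool.

    Pools map level name → list of slice references (paths, ids — opaque to
    this module).  Raises ``ValueError`` when a pool cannot supply the
    requested count.  The global presentation order is a seeded permutation.
    """
    rng = np.random.default_rng(seed)
    records = []
    for level in levels:
        for source, pool, count in (
            ("human", human_pool, per_level_human),
            ("automatic", auto_pool, per_level_auto),
        ):
            avail = pool.get(level, [])
            if len(avail) < count:
                raise ValueError(
                    f"{source} pool has {len(avail)} slices at {level}, "
                    f"need {count}"
                )
            picks = rng.choice(len(avail), size=count, replace=False)
            for p in picks:
                records.append({"level_name": level, "source": source,
                                "slice_ref": avail[int(p)]})
    order = rng.permutation(len(records))
    blinding = {}
    rows = []
    for item_id, k in enumerate(order):
        rec = records[int(k)]
        blinding[item_id] = rec["source"]
        rows.append({"item_id": item_id, "level_name": rec["level_name"],
                     "slice_ref": rec["slice_ref"]})
    return ReviewSession(pd.DataFrame(rows), blinding, seed)


def _chi2(table: pd.DataFrame, correction: bool) -> dict:
    """Chi-squared on a contingency table; degenerate tables are flagged."""
    arr = table.to_numpy()
    if arr.shape[0] < 2 or arr.shape[1] < 2 or (arr.sum(axis=0) == 0).any():
        return {"statistic": None, "pvalue": None, "dof": None, "degenerate": True}
    res = stats.chi2_contingency(arr, correction=correction)
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue),
            "dof": int(res.dof), "degenerate": False}


def analyze_review(session: ReviewSession, correction: bool = True) -> dict:
    """Unblind and summarise a completed session.

    Returns identification accuracy (how often raters spotted the true
    source), per-source rating distributions and clinical-acceptability
    proportions (ratings 3–4), and chi-squared tests on the source×guess
    and source×rating tables.  Requires every item to be answered.
    """
    missing = set(session.blinding) - set(session.responses)
    if missing:
        raise ValueError(f"{len(missing)} items unanswered")
    df = pd.DataFrame(
        {
            "item_id": list(session.responses),
            "guess": [g for g, _ in session.responses.values()],
            "rating": [r for _, r in session.responses.values()],
        }
    )
    df["source"] = df["item_id"].map(session.blinding)

    guess_table = pd.crosstab(df["source"], df["guess"]).reindex(
        index=SOURCES, columns=SOURCES, fill_value=0)
    rating_table = pd.crosstab(df["source"], df["rating"]).reindex(
        index=SOURCES, columns=RATING_SCALE, fill_value=0)
    acceptability = {
        src: float(df.loc[df["source"] == src, "rating"].isin(ACCEPTABLE_RATINGS).mean())
        for src in SOURCES
        if (df["source"] == src).any()
    }
    return {
        "n_items": len(df),
        "identification_accuracy": float((df["guess"] == df["source"]).mean()),
        "guess_table": guess_table,
        "rating_table": rating_table,
        "acceptability": acceptability,
        "chi2_source_vs_guess": _chi2(guess_table, correction),
        "chi2_source_vs_rating": _chi2(rating_table, correction),
    }
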