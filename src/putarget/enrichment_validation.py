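"""External validation of predicted target sets by gene-list overlap.

A predicted-target set is compared with an independent reference list
(e.g. literature-proposed targets) over a fixed gene universe, after
removing genes the model trained or tested on.  Significance comes from a
two-sided Fisher's exact test (minimum-likelihood convention) on the 2x2
membership table; the sample odds ratio (a*d)/(b*c) measures effect size.
A permutation null — both sets redrawn uniformly at random with their
sizes fixed — shows what overlap chance alone produces (odds ratios
centred on 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 overlap table [[a, b], [c, d]] with its exact test.

    a = in both sets, b = predicted only, c = reference only,
    d = in neither.  ``odds_ratio`` is (a*d)/(b*c); it is NaN (and
    ``odds_ratio_defined`` False) when b*c = 0.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    universe_size: int

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))

    @property
    def odds_ratio_defined(self) -> bool:
        return math.isfinite(self.odds_ratio)

    def to_dict(self) -> dict:
        return {
            "table": [[self.a, self.b], [self.c, self.d]],
            "odds_ratio": None if not math.isfinite(self.odds_ratio) else self.odds_ratio,
            "odds_ratio_defined": self.odds_ratio_defined,
            "p_value": self.p_value,
            "universe_size": self.universe_size,
        }


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def _table_from_counts(a: int, n_pred: int, n_ref: int, universe: int) -> EnrichmentResult:
    b = n_pred - a
    c = n_ref - a
    d = universe - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=_sample_odds_ratio(a, b, c, d),
        p_value=float(p),
        universe_size=universe,
    )


def overlap_enrichment(
    predicted: Iterable[str],
    reference: Iterable[str],
    exclusions: Iterable[str] = (),
    universe_size: int = 19_000,
) -> EnrichmentResult:
    """Fisher's exact test of the overlap between two gene sets.

    ``exclusions`` (typically the training and test genes) are removed from
    both sets before the table is built.  ``universe_size`` should count the
    genes either set could in principle contain (default 19,000, roughly
    the protein-coding genome).
    """
    excl = set(exclusions)
    pred = set(predicted) - excl
    ref = set(reference) - excl
    union = len(pred | ref)
    if universe_size < union:
        raise ValueError(
            f"universe_size {universe_size} smaller than |predicted ∪ reference| = {union}"
        )
    a = len(pred & ref)
    return _table_from_counts(a, len(pred), len(ref), universe_size)


def permutation_null(
    predicted_size: int,
    reference_size: int,
    universe_size: int,
    config: PermutationConfig | None = None,
) -> pd.DataFrame:
    """Null distribution of the overlap test under random set membership.

    Each permutation draws two independent uniform random gene sets of the
    stated sizes from the universe and runs the same exact test.  Returns a
    frame with per-permutation ``overlap``, ``odds_ratio`` and ``p_value``;
    summarise with .mean() / .std().
    """
    config = config or PermutationConfig()
    if predicted_size > universe_size or reference_size > universe_size:
        raise ValueError("set sizes exceed the universe")
    rng = np.random.default_rng(config.seed)

    @lru_cache(maxsize=None)
    def result_for_overlap(a: int) -> tuple[float, float]:
        res = _table_from_counts(a, predicted_size, reference_size, universe_size)
        return res.odds_ratio, res.p_value

    rows = []
    members = np.arange(universe_size)
    for _ in range(config.n_permutations):
        set_a = rng.choice(members, size=predicted_size, replace=False)
        set_b = rng.choice(members, size=reference_size, replace=False)
        mask = np.zeros(universe_size, dtype=bool)
        mask[set_a] = True
        overlap = int(mask[set_b].sum())
        oratio, p = result_for_overlap(overlap)
        rows.append({"overlap": overlap, "odds_ratio": oratio, "p_value": p})
    return pd.DataFrame(rows)
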