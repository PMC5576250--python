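"""Positive-unlabelled labelling from development stages, and set construction.

A gene is a positive if any of its drug programmes reached an active
development stage (Preclinical through Launched); genes with only
suspended/discontinued/withdrawn programmes, or absent from the stage table,
stay unlabelled and are treated as negatives for training (the PU device).
The working dataset balances all positives against an equal-size random
sample of unlabelled genes; the rest of the unlabelled genes form the
prediction set.  The working set is split 80/20 into train and test,
stratified by label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Active development stages that define a positive label, in precedence
#: order from least to most advanced.
POSITIVE_STAGES: tuple[str, ...] = (
    "Preclinical",
    "Clinical Trial",
    "Phase I Clinical Trial",
    "Phase II Clinical Trial",
    "Phase III Clinical Trial",
    "Pre-registration",
    "Registered",
    "Launched",
)

#: Failed-programme categories; genes with only these stay unlabelled.
FAILED_STAGES: tuple[str, ...] = ("Suspended", "Discontinued", "Withdrawn")

_STAGE_RANK = {s: i for i, s in enumerate(POSITIVE_STAGES)}


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.8
    balanced: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def assign_labels(
    stage_records: pd.DataFrame,
    gene_universe: Iterable[str],
    positive_stages: Sequence[str] = POSITIVE_STAGES,
    failed_stages: Sequence[str] = FAILED_STAGES,
) -> pd.DataFrame:
    """Label every gene in the universe from its development-stage rows.

    ``stage_records`` needs columns ``gene`` and ``stage``.  A gene is
    labelled 1 iff it has at least one positive stage; its ``best_stage`` is
    the most advanced such stage under the precedence order.  Genes with only
    failed stages, or with no rows at all, are labelled 0 with best_stage
    NA.  Rows with a stage outside both vocabularies are rejected with a
    warning.

    Returns a frame indexed by gene with columns ``label`` (int 0/1) and
    ``best_stage``.
    """
    universe = pd.Index(sorted({str(g) for g in gene_universe}), name="gene")
    rank = {s: i for i, s in enumerate(positive_stages)}
    known = set(positive_stages) | set(failed_stages)

    out = pd.DataFrame({"label": 0, "best_stage": pd.NA}, index=universe)
    if len(stage_records):
        bad = ~stage_records["stage"].isin(known)
        if bad.any():
            for _, row in stage_records[bad].iterrows():
                logger.warning("unknown stage %r for gene %s; record rejected",
                               row["stage"], row["gene"])
        recs = stage_records[~bad]
        pos = recs[recs["stage"].isin(positive_stages)]
        if len(pos):
            best = (
                pos.assign(rank=pos["stage"].map(rank))
                .groupby("gene")["rank"]
                .max()
                .map(dict(enumerate(positive_stages)))
            )
            best = best[best.index.isin(universe)]
            out.loc[best.index, "label"] = 1
            out.loc[best.index, "best_stage"] = best
    return out


def make_working_split(
    labels: pd.DataFrame,
    config: SplitConfig | None = None,
) -> pd.Series:
    """Partition the gene universe into train / test / prediction sets.

    All P positives plus P unlabelled genes sampled without replacement form
    the balanced working set; the remaining unlabelled genes become the
    prediction set.  The working set is split into train and test with the
    test share floored per class (so 2,842 genes at 80/20 give 2,274 train
    and 568 test), which keeps the classes balanced within each part.

    Returns a Series of partition tags ("train" | "test" | "prediction")
    indexed like ``labels``.
    """
    config = config or SplitConfig()
    rng = np.random.default_rng(config.seed)

    y = labels["label"].astype(int)
    positives = y.index[y == 1]
    unlabelled = y.index[y == 0]
    if len(positives) < 2:
        raise ValueError(f"need >=2 positives, got {len(positives)}")
    if len(unlabelled) < len(positives):
        raise ValueError(
            f"unlabelled pool ({len(unlabelled)}) smaller than positives ({len(positives)})"
        )

    sampled = pd.Index(
        rng.choice(np.asarray(unlabelled), size=len(positives), replace=False)
    )
    partition = pd.Series("prediction", index=y.index, name="partition")

    for members in (positives, sampled):
        members = np.asarray(members)
        perm = rng.permutation(len(members))
        n_test = int(np.floor(len(members) * (1.0 - config.train_fraction) + 1e-9))
        n_test = max(n_test, 1)
        test_idx = members[perm[:n_test]]
        train_idx = members[perm[n_test:]]
        partition.loc[test_idx] = "test"
        partition.loc[train_idx] = "train"
    return partition


def partition_counts(partition: pd.Series) -> dict[str, int]:
    """Convenience tally of partition sizes (train/test/prediction/working)."""
    counts = partition.value_counts().to_dict()
    counts = {k: int(counts.get(k, 0)) for k in ("train", "test", "prediction")}
    counts["working"] = counts["train"] + counts["test"]
    return counts
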