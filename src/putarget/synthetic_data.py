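"""Synthetic gene-disease evidence with known ground truth.

The real inputs of this analysis (an association dump and a commercial
drug-pipeline database) are licensed and cannot be redistributed, so this
module generates inputs with the statistical structure the method assumes:

* a sparse evidence table — for most (gene, disease, data type) triples no
  record exists; when one does, its score follows a Beta distribution
  (a zero-inflated Beta model overall, matching a matrix in which most
  values sit close to zero);
* class signal concentrated in the animal_model, rna_expression and
  genetic_association channels: true targets activate those channels more
  often and with higher scores;
* a known_drug channel that also tracks the true class (which is exactly
  why the feature builder excludes it);
* positive labels that are a uniform random subset of the true targets
  (the SCAR — selected completely at random — assumption), leaving the
  unlabelled class contaminated with hidden positives;
* a development-stage table in which observed positives carry active-stage
  rows and a configurable fraction of the remaining genes carries
  failed-programme rows;
* a literature gene list enriched for true targets by a configurable factor.

All draws are functions of explicit seeds, so record streams are
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence_features import DATA_TYPES, write_evidence
from .labelling_splits import FAILED_STAGES, POSITIVE_STAGES

#: Channels carrying class signal by default (plus known_drug, which leaks
#: the label by construction and is excluded from the features downstream).
SIGNAL_DATA_TYPES: tuple[str, ...] = (
    "animal_model",
    "rna_expression",
    "genetic_association",
)


class SyntheticConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Activation probabilities may be a single float applied to every data
    type or a mapping from data-type name to float.  For data types not in
    ``signal_features`` (and not known_drug) the background probability and
    score shape apply to both classes, so those channels carry no signal.
    """

    n_genes: int = 2000
    n_diseases: int = 50
    true_target_fraction: float = 0.08
    labelled_fraction: float = 0.5
    signal_features: tuple[str, ...] = SIGNAL_DATA_TYPES
    activation_prob_target: float | Mapping[str, float] = 0.15
    activation_prob_background: float | Mapping[str, float] = 0.08
    score_shape_target: tuple[float, float] = (1.5, 3.0)
    score_shape_background: tuple[float, float] = (1.0, 4.0)
    indirect_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise SyntheticConfigError("n_genes must be >= 2")
        if self.n_diseases < 1:
            raise SyntheticConfigError("n_diseases must be >= 1")
        if not 0.0 < self.true_target_fraction < 1.0:
            raise SyntheticConfigError("true_target_fraction must lie in (0, 1)")
        if not 0.0 < self.labelled_fraction <= 1.0:
            raise SyntheticConfigError("labelled_fraction must lie in (0, 1]")
        if not 0.0 <= self.indirect_fraction <= 1.0:
            raise SyntheticConfigError("indirect_fraction must lie in [0, 1]")
        unknown = set(self.signal_features) - set(DATA_TYPES)
        if unknown:
            raise SyntheticConfigError(f"unknown signal features: {sorted(unknown)}")
        for dt in DATA_TYPES:
            p_t = self.activation_for(dt, target=True)
            p_b = self.activation_for(dt, target=False)
            for p in (p_t, p_b):
                if not 0.0 <= p <= 1.0:
                    raise SyntheticConfigError(f"activation probability {p} outside [0, 1]")
            if dt in self.signal_features and p_t < p_b:
                raise SyntheticConfigError(
                    f"{dt}: target activation {p_t} below background {p_b}"
                )
        for shape in (self.score_shape_target, self.score_shape_background):
            if len(shape) != 2 or shape[0] <= 0 or shape[1] <= 0:
                raise SyntheticConfigError(f"Beta shape parameters must be positive: {shape}")

    def activation_for(self, datatype: str, target: bool) -> float:
        """Activation probability for one data type and class."""
        src = self.activation_prob_target if target else self.activation_prob_background
        p = src.get(datatype, 0.0) if isinstance(src, Mapping) else float(src)
        # non-signal channels are class-blind; known_drug mirrors the label
        if not target:
            return p
        if datatype in self.signal_features or datatype == "known_drug":
            return p
        return self.activation_for(datatype, target=False)


def _gene_ids(n: int) -> np.ndarray:
    return np.array([f"G{i:06d}" for i in range(n)])


def generate_evidence(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the evidence table and its ground truth.

    Returns ``(records, truth)``: records with columns
    ``gene, disease, datatype, score, is_direct`` and truth indexed by gene
    with boolean columns ``true_target`` and ``observed_positive``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    diseases = np.array([f"D{i:04d}" for i in range(config.n_diseases)])

    is_target = rng.random(config.n_genes) < config.true_target_fraction
    observed = is_target & (rng.random(config.n_genes) < config.labelled_fraction)
    truth = pd.DataFrame(
        {"true_target": is_target, "observed_positive": observed},
        index=pd.Index(genes, name="gene"),
    )

    frames: list[pd.DataFrame] = []
    a_t, b_t = config.score_shape_target
    a_b, b_b = config.score_shape_background
    for dt in DATA_TYPES:
        p = np.where(
            is_target,
            config.activation_for(dt, target=True),
            config.activation_for(dt, target=False),
        )
        active = rng.random((config.n_genes, config.n_diseases)) < p[:, None]
        gi, di = np.nonzero(active)
        if len(gi) == 0:
            continue
        signal_dt = dt in config.signal_features or dt == "known_drug"
        from_target = is_target[gi] & signal_dt
        scores = np.where(
            from_target,
            rng.beta(a_t, b_t, size=len(gi)),
            rng.beta(a_b, b_b, size=len(gi)),
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes[gi],
                    "disease": diseases[di],
                    "datatype": dt,
                    "score": scores,
                    "is_direct": rng.random(len(gi)) >= config.indirect_fraction,
                }
            )
        )
    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = pd.DataFrame(columns=["gene", "disease", "datatype", "score", "is_direct"])
    return records, truth


def generate_stage_table(
    truth: pd.DataFrame,
    multi_stage_prob: float = 0.3,
    failed_stage_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw development-stage rows consistent with the ground truth.

    Every observed positive receives one active stage uniformly at random,
    plus (with probability ``multi_stage_prob``) a second, distinct one —
    exercising the most-advanced-stage rule.  A fraction
    ``failed_stage_fraction`` of the remaining genes receives one
    failed-programme stage, exercising the exclusion logic.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str]] = []
    positives = truth.index[truth["observed_positive"].astype(bool)]
    others = truth.index[~truth["observed_positive"].astype(bool)]

    for gene in positives:
        stages = [rng.choice(POSITIVE_STAGES)]
        if rng.random() < multi_stage_prob:
            remaining = [s for s in POSITIVE_STAGES if s != stages[0]]
            stages.append(rng.choice(remaining))
        rows.extend((gene, str(s)) for s in stages)
    for gene in others:
        if rng.random() < failed_stage_fraction:
            rows.append((gene, str(rng.choice(FAILED_STAGES))))
    return pd.DataFrame(rows, columns=["gene", "stage"])


def generate_literature_list(
    truth: pd.DataFrame,
    enrichment_factor: float = 5.0,
    size: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a gene list enriched for true targets.

    Genes are drawn without replacement with weight ``enrichment_factor``
    for true targets and 1 otherwise; a factor of 1 gives a uniform random
    list.  Emulates a text-mined list of literature-proposed targets.
    """
    if enrichment_factor < 1.0:
        raise SyntheticConfigError("enrichment_factor must be >= 1")
    if size > len(truth):
        raise SyntheticConfigError(f"size {size} exceeds universe {len(truth)}")
    rng = np.random.default_rng(seed)
    if size == 0:
        return pd.DataFrame(columns=["gene"])
    weights = np.where(truth["true_target"].astype(bool), enrichment_factor, 1.0)
    chosen = rng.choice(
        np.asarray(truth.index), size=size, replace=False, p=weights / weights.sum()
    )
    return pd.DataFrame({"gene": sorted(chosen)})


def write_synthetic_inputs(
    outdir: str | Path,
    config: SyntheticConfig,
    multi_stage_prob: float = 0.3,
    failed_stage_fraction: float = 0.1,
    literature_enrichment: float = 5.0,
    literature_size: int | None = None,
) -> dict[str, Path]:
    """Generate and write the full set of pipeline input files.

    Writes evidence as JSON-lines and TSV, the stage table and literature
    list as TSV, and the ground truth as TSV (for tests only).  Per-stage
    seeds are derived deterministically from ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_evidence(config)
    children = np.random.SeedSequence(config.seed).spawn(2)
    stage_seed, lit_seed = (int(c.generate_state(1)[0] % 2**31) for c in children)
    stages = generate_stage_table(truth, multi_stage_prob, failed_stage_fraction, stage_seed)
    if literature_size is None:
        literature_size = max(1, config.n_genes // 10)
    literature = generate_literature_list(
        truth, literature_enrichment, literature_size, lit_seed
    )

    paths = {
        "evidence_jsonl": outdir / "evidence.jsonl",
        "evidence_tsv": outdir / "evidence.tsv",
        "stages": outdir / "stages.tsv",
        "literature": outdir / "literature.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_evidence(records, paths["evidence_jsonl"], fmt="jsonl")
    write_evidence(records, paths["evidence_tsv"], fmt="tsv")
    stages.to_csv(paths["stages"], sep="\t", index=False)
    literature.to_csv(paths["literature"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t")
    return paths
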