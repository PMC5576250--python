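"""Aggregate gene-disease evidence records into a per-gene feature matrix.

Evidence comes as one record per (gene, disease, data type) triple with an
association score in [0, 1], following the layout of the Open Targets
association dump.  Seven data types exist; five are kept as features.  The
``known_drug`` channel is discarded because it restates the prediction
target, and ``literature`` is discarded because it is reserved for external
validation.  Animal-model records below a confidence threshold (default 0.4)
are dropped before any averaging, indirect (ontology-propagated)
associations are removed, and the surviving scores are averaged per gene and
data type across diseases, yielding a single row per gene.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The seven evidence channels of the association dump, in canonical order.
DATA_TYPES: tuple[str, ...] = (
    "affected_pathway",
    "animal_model",
    "genetic_association",
    "rna_expression",
    "somatic_mutation",
    "known_drug",
    "literature",
)

#: The five channels used as model features, in design-matrix column order.
FEATURE_DATA_TYPES: tuple[str, ...] = (
    "affected_pathway",
    "animal_model",
    "genetic_association",
    "rna_expression",
    "somatic_mutation",
)

EVIDENCE_COLUMNS = ("gene", "disease", "datatype", "score", "is_direct")


class EvidenceReadError(RuntimeError):
    """Raised when an evidence file cannot be read at all."""


@dataclass(frozen=True)
class FeatureConfig:
    """Settings for turning raw evidence into the design matrix.

    ``animal_model_min_score`` is applied to individual records before
    averaging when ``record_level_filter`` is true (the default); setting it
    to false instead zeroes aggregated animal_model cells below the
    threshold, for sensitivity analysis.
    """

    used_data_types: tuple[str, ...] = FEATURE_DATA_TYPES
    animal_model_min_score: float = 0.4
    drop_indirect: bool = True
    excluded_data_types: tuple[str, ...] = ("known_drug", "literature")
    record_level_filter: bool = True

    def __post_init__(self) -> None:
        overlap = set(self.used_data_types) & set(self.excluded_data_types)
        if overlap:
            raise ValueError(f"data types both used and excluded: {sorted(overlap)}")
        if not 0.0 <= self.animal_model_min_score <= 1.0:
            raise ValueError("animal_model_min_score must lie in [0, 1]")
        unknown = set(self.used_data_types) - set(DATA_TYPES)
        if unknown:
            raise ValueError(f"unknown data types: {sorted(unknown)}")


def read_evidence(path: str | Path, fmt: str = "jsonl") -> tuple[pd.DataFrame, list[str]]:
    """Read evidence records from JSON-lines or TSV.

    Returns the well-formed records as a DataFrame with columns
    ``gene, disease, datatype, score, is_direct`` plus a list of per-line
    error messages (malformed lines, unknown data types, out-of-range
    scores).  Rejected lines are excluded from the frame.
    """
    path = Path(path)
    if not path.exists():
        raise EvidenceReadError(f"evidence file not found: {path}")
    if fmt not in ("jsonl", "tsv"):
        raise ValueError(f"unknown evidence format: {fmt!r}")

    rows: list[dict] = []
    errors: list[str] = []
    with open(path) as fh:
        if fmt == "tsv":
            header = fh.readline().rstrip("\n").split("\t")
            if header != list(EVIDENCE_COLUMNS):
                raise EvidenceReadError(f"bad TSV header in {path}: {header}")
        for lineno, line in enumerate(fh, start=2 if fmt == "tsv" else 1):
            line = line.strip()
            if not line:
                continue
            try:
                if fmt == "jsonl":
                    rec = json.loads(line)
                else:
                    parts = line.split("\t")
                    if len(parts) != 5:
                        raise ValueError(f"expected 5 fields, got {len(parts)}")
                    rec = {
                        "gene": parts[0],
                        "disease": parts[1],
                        "datatype": parts[2],
                        "score": float(parts[3]),
                        "is_direct": parts[4].lower() in ("true", "1"),
                    }
                score = float(rec["score"])
            except (ValueError, KeyError, TypeError, json.JSONDecodeError) as exc:
                errors.append(f"line {lineno}: malformed record ({exc})")
                continue
            if rec["datatype"] not in DATA_TYPES:
                errors.append(f"line {lineno}: unknown data type {rec['datatype']!r}")
                continue
            if not 0.0 <= score <= 1.0:
                errors.append(f"line {lineno}: score {score} outside [0, 1]")
                continue
            rows.append(
                {
                    "gene": str(rec["gene"]),
                    "disease": str(rec["disease"]),
                    "datatype": rec["datatype"],
                    "score": score,
                    "is_direct": bool(rec["is_direct"]),
                }
            )
    if errors:
        logger.warning("%s: %d records rejected", path, len(errors))
    if not rows:
        logger.warning("%s: no valid evidence records", path)
        return pd.DataFrame(columns=list(EVIDENCE_COLUMNS)), errors
    return pd.DataFrame(rows, columns=list(EVIDENCE_COLUMNS)), errors


def write_evidence(records: pd.DataFrame, path: str | Path, fmt: str = "jsonl") -> None:
    """Write evidence records as JSON-lines or TSV (inverse of read_evidence)."""
    path = Path(path)
    if fmt == "jsonl":
        with open(path, "w") as fh:
            for rec in records[list(EVIDENCE_COLUMNS)].to_dict("records"):
                rec["is_direct"] = bool(rec["is_direct"])
                fh.write(json.dumps(rec) + "\n")
    elif fmt == "tsv":
        out = records[list(EVIDENCE_COLUMNS)].copy()
        out["is_direct"] = out["is_direct"].map({True: "true", False: "false"})
        out.to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown evidence format: {fmt!r}")


def build_feature_matrix(
    records: pd.DataFrame,
    config: FeatureConfig | None = None,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Build the genes x data-types design matrix of pan-disease mean scores.

    Filtering happens in this order: excluded data types out, indirect
    associations out (if configured), sub-threshold animal_model records out,
    then the mean score per (gene, data type) is taken over the diseases that
    retain at least one record.  Combinations with no surviving evidence are
    encoded as 0.  Rows cover every gene with >=1 retained record plus any
    gene in ``universe``.
    """
    config = config or FeatureConfig()
    cols = list(config.used_data_types)

    df = records
    if len(df):
        df = df[df["datatype"].isin(cols)]
        if config.drop_indirect:
            df = df[df["is_direct"].astype(bool)]
        if config.record_level_filter and "animal_model" in cols:
            keep = (df["datatype"] != "animal_model") | (
                df["score"] >= config.animal_model_min_score
            )
            df = df[keep]

    if len(df):
        # one pan-disease mean per (gene, datatype); diseases without retained
        # evidence do not enter the denominator
        agg = df.groupby(["gene", "datatype"], observed=True)["score"].mean()
        matrix = agg.unstack("datatype")
    else:
        matrix = pd.DataFrame(columns=cols)

    matrix = matrix.reindex(columns=cols)
    if universe is not None:
        all_genes = matrix.index.union(pd.Index([str(g) for g in universe]))
        matrix = matrix.reindex(all_genes)
    matrix = matrix.astype(float).fillna(0.0)

    if not config.record_level_filter and "animal_model" in cols:
        col = matrix["animal_model"]
        matrix["animal_model"] = col.where(col >= config.animal_model_min_score, 0.0)

    matrix = matrix.sort_index()
    matrix.index.name = "gene"
    return matrix


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write the design matrix as TSV with full float precision."""
    matrix.to_csv(path, sep="\t", index=True, index_label="gene", float_format="%.17g")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a design matrix written by write_feature_matrix (exact round trip)."""
    matrix = pd.read_csv(path, sep="\t", index_col="gene", dtype={0: str})
    matrix.index = matrix.index.astype(str)
    return matrix.astype(float)
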