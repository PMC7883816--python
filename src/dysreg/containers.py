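"""Core in-memory containers shared across the pipeline.

The pipeline moves expression data through three shapes: a raw feature-level
table (TPM or array intensities, possibly with missing entries), a clean
gene-level log2 matrix with per-sample condition labels, and edge tables for
the regulatory networks.  Everything is pandas underneath; the thin dataclass
wrappers carry the metadata (platform, condition labels, pairing) that a bare
DataFrame would lose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NORMAL = "normal"
TUMOR = "tumor"
CONDITIONS = (NORMAL, TUMOR)


@dataclass
class RawExpressionTable:
    """Feature x sample expression before preprocessing.

    ``values`` rows are genes or probes, columns are samples.  ``platform``
    is ``"rnaseq_tpm"`` (linear TPM, non-negative) or ``"microarray"``
    (linear or log intensities).  ``n_genes_removed`` is filled in by the
    filtering step so the CLI can report it.
    """

    values: pd.DataFrame
    platform: str = "rnaseq_tpm"
    n_genes_removed: int = 0

    def __post_init__(self) -> None:
        if self.platform not in ("rnaseq_tpm", "microarray"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.platform == "rnaseq_tpm":
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("negative values in TPM table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ExpressionMatrix:
    """Gene x sample log2 expression with condition labels.

    ``condition`` maps every sample to ``normal`` or ``tumor``; ``pairing``
    optionally maps each tumor sample to its matched normal.
    """

    values: pd.DataFrame
    condition: pd.Series
    pairing: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("ExpressionMatrix must not contain missing values")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        self.condition = pd.Series(self.condition)
        missing = set(self.values.columns) - set(self.condition.index)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)[:5]} ...")
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels {bad}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_condition(self, condition: str) -> "ExpressionMatrix":
        """Restrict to samples of one condition."""
        keep = [s for s in self.values.columns if self.condition.get(s) == condition]
        return ExpressionMatrix(self.values[keep], self.condition[keep], None)


@dataclass
class PrepConfig:
    """Preprocessing thresholds.

    min_tpm
        TPM values below this are treated as missing (default 1).
    max_missing_frac
        genes whose missing fraction strictly exceeds this are dropped
        (default 0.2).
    knn_k
        neighbour count for k-nearest-gene imputation (default 10).
    already_log
        microarray tables already in log space skip the log2 transform.
    """

    min_tpm: float = 1.0
    max_missing_frac: float = 0.2
    knn_k: int = 10
    already_log: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.max_missing_frac < 1:
            raise ValueError("max_missing_frac must be in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclass
class ReferenceGRN:
    """Candidate TF->target network from promoter motif scanning.

    ``edges`` columns: tf, target, score (best site log-odds), p_promoter
    (promoter-level p of the best hit).  (tf, target) pairs are unique.
    """

    edges: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["tf", "target", "score", "p_promoter"]))

    def __post_init__(self) -> None:
        required = {"tf", "target", "score", "p_promoter"}
        if not required.issubset(self.edges.columns):
            raise ValueError(f"edge table needs columns {sorted(required)}")
        if self.edges.duplicated(["tf", "target"]).any():
            raise ValueError("duplicate (tf, target) edges")

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())

    def targets_of(self, tf: str) -> list[str]:
        return list(self.edges.loc[self.edges["tf"] == tf, "target"])

    def candidate_tfs(self, target: str) -> list[str]:
        return sorted(self.edges.loc[self.edges["target"] == target, "tf"])

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class ConditionalGRN:
    """Reference network pruned to links supported by expression in one
    condition; ``edges`` maps target -> set of confirmed TFs."""

    condition: str
    edges: dict[str, set[str]]

    def __post_init__(self) -> None:
        self.edges = {t: set(tfs) for t, tfs in self.edges.items() if tfs}

    def n_links(self) -> int:
        return sum(len(v) for v in self.edges.values())

    def tfs_of(self, target: str) -> set[str]:
        return self.edges.get(target, set())

    def assert_subset_of(self, ref: ReferenceGRN) -> None:
        ref_pairs = set(zip(ref.edges["tf"], ref.edges["target"]))
        for target, tfs in self.edges.items():
            for tf in tfs:
                if (tf, target) not in ref_pairs:
                    raise AssertionError(
                        f"conditional edge {tf}->{target} absent from reference GRN")
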