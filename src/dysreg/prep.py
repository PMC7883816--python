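"""Expression preprocessing: masking, filtering, kNN imputation, probe
collapse, log2 transform and quantile normalization.

RNA-seq input is TPM; values below ``min_tpm`` are treated as missing and
genes missing in more than ``max_missing_frac`` of samples are dropped
before k-nearest-gene imputation.  Microarray input is collapsed from probe
to gene level first (multi-gene probes removed, the highest-mean probe kept
per gene), then imputed/normalized the same way.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, PrepConfig, RawExpressionTable


def mask_and_filter(table: RawExpressionTable, cfg: PrepConfig | None = None) -> RawExpressionTable:
    """Mask sub-threshold TPM values as missing and drop genes with too
    many missing entries.

    Entries strictly below ``cfg.min_tpm`` become NaN; a gene is removed
    when its missing fraction strictly exceeds ``cfg.max_missing_frac``.
    """
    cfg = cfg or PrepConfig()
    if table.platform != "rnaseq_tpm":
        raise ValueError("mask_and_filter applies to rnaseq_tpm tables only")
    values = table.values.where(table.values >= cfg.min_tpm)
    missing_frac = values.isna().mean(axis=1)
    keep = missing_frac <= cfg.max_missing_frac
    removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("no genes survive filtering")
    return RawExpressionTable(values.loc[keep], platform=table.platform,
                              n_genes_removed=removed)


def impute_knn(table: RawExpressionTable, k: int = 10) -> RawExpressionTable:
    """Fill missing entries from the k nearest genes.

    Distance between two genes is the root mean squared difference over
    samples observed in both; donors sharing fewer than 3 observed samples
    with the target gene, or unobserved in the sample being imputed, are
    skipped.  The imputed value is the unweighted mean of the k nearest
    eligible donors' values in that sample.  Observed entries are untouched.
    """
    values = table.values
    arr = values.to_numpy(dtype=float)
    n_genes, n_samples = arr.shape
    obs = ~np.isnan(arr)
    if (obs.sum(axis=1) == 0).any():
        bad = values.index[obs.sum(axis=1) == 0]
        raise ValueError(f"genes with zero observed values: {list(bad[:5])}")
    if not np.isnan(arr).any():
        return table
    if k >= n_genes:
        raise ValueError("k must be smaller than the number of genes")

    out = arr.copy()
    need = np.where(~obs.all(axis=1))[0]
    for gi in need:
        shared = obs & obs[gi]                       # donors' overlap with target
        n_shared = shared.sum(axis=1)
        diff = arr - arr[gi]
        sq = np.where(shared, diff * diff, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(sq / n_shared)
        dist[gi] = np.inf
        # donors need >= 3 mutually observed samples (or all of the target's
        # observed samples when it has fewer than 3)
        min_shared = min(3, int(obs[gi].sum()))
        dist[n_shared < min_shared] = np.inf
        for si in np.where(~obs[gi])[0]:
            cand = dist.copy()
            cand[~obs[:, si]] = np.inf               # donor must be observed here
            order = np.argsort(cand, kind="stable")[:k]
            order = order[np.isfinite(cand[order])]
            if len(order) == 0:
                raise ValueError(
                    f"no eligible donors for gene {values.index[gi]} sample "
                    f"{values.columns[si]}")
            out[gi, si] = arr[order, si].mean()
    return RawExpressionTable(pd.DataFrame(out, index=values.index, columns=values.columns),
                              platform=table.platform,
                              n_genes_removed=table.n_genes_removed)


def log2_transform(table: RawExpressionTable) -> pd.DataFrame:
    """Elementwise log2; all values must be positive."""
    arr = table.values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("impute before log2 transform")
    if (arr <= 0).any():
        raise ValueError("non-positive value encountered in log2 transform")
    return pd.DataFrame(np.log2(arr), index=table.values.index,
                        columns=table.values.columns)


def collapse_probes(table: RawExpressionTable, probe_map: dict[str, set[str]]) -> RawExpressionTable:
    """Collapse a probe-level microarray table to gene level.

    Probes mapping to more than one gene are removed; when several probes
    map to one gene the probe with the highest mean across samples is kept
    (ties broken by lexicographic probe id).
    """
    if table.platform != "microarray":
        raise ValueError("collapse_probes applies to microarray tables")
    if not probe_map:
        raise ValueError("empty probe map")
    rows = []
    for probe in table.values.index:
        genes = probe_map.get(str(probe))
        if genes is None or len(genes) != 1:
            continue                                  # unmapped or multi-gene probe
        rows.append((next(iter(genes)), str(probe)))
    if not rows:
        raise ValueError("no single-gene probes to collapse")
    means = table.values.mean(axis=1)
    chosen: dict[str, str] = {}
    for gene, probe in sorted(rows, key=lambda gp: (gp[0], -means[gp[1]], gp[1])):
        chosen.setdefault(gene, probe)
    genes_sorted = sorted(chosen)
    out = table.values.loc[[chosen[g] for g in genes_sorted]]
    out.index = pd.Index(genes_sorted, name="gene")
    return RawExpressionTable(out, platform="microarray",
                              n_genes_removed=table.n_genes_removed)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the mean order-statistic distribution.

    Rank ties within a column receive the mean of the reference values at
    the tied ranks, which makes the operation idempotent.
    """
    if values.shape[1] < 2:
        warnings.warn("single sample: quantile normalization is a no-op")
        return values.copy()
    arr = values.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average")   # 1-based, fractional on ties
        out[:, j] = np.interp(ranks, np.arange(1, len(ref) + 1), ref)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def preprocess_rnaseq(table: RawExpressionTable, condition: pd.Series,
                      pairing: dict[str, str] | None = None,
                      cfg: PrepConfig | None = None) -> tuple[ExpressionMatrix, dict]:
    """Full RNA-seq pipeline: mask/filter -> kNN impute -> log2 -> quantile.

    Returns the clean matrix and a report dict (genes dropped, entries
    imputed).
    """
    cfg = cfg or PrepConfig()
    filtered = mask_and_filter(table, cfg)
    n_missing = int(filtered.values.isna().sum().sum())
    imputed = impute_knn(filtered, k=cfg.knn_k) if n_missing else filtered
    logged = log2_transform(imputed)
    normed = quantile_normalize(logged)
    report = {"genes_dropped": filtered.n_genes_removed, "entries_imputed": n_missing,
              "genes_kept": int(normed.shape[0]), "samples": int(normed.shape[1])}
    return ExpressionMatrix(normed, condition, pairing), report


def preprocess_microarray(table: RawExpressionTable, probe_map: dict[str, set[str]],
                          condition: pd.Series,
                          pairing: dict[str, str] | None = None,
                          cfg: PrepConfig | None = None) -> tuple[ExpressionMatrix, dict]:
    """Microarray pipeline: probe collapse -> (log2 unless already_log) ->
    quantile normalization.  Arrays are assumed complete after collapse."""
    cfg = cfg or PrepConfig()
    collapsed = collapse_probes(table, probe_map)
    values = collapsed.values if cfg.already_log else log2_transform(collapsed)
    normed = quantile_normalize(values)
    report = {"probes_in": len(table.values), "genes_kept": int(normed.shape[0]),
              "samples": int(normed.shape[1])}
    return ExpressionMatrix(normed, condition, pairing), report
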