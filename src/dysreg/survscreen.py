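"""Prognostic screening of dysregulations against randomized controls.

Each dysregulation contributes a gene pair; for each of the four model
types (OS/RFS endpoint, with or without the clinical covariates age,
gender, stage) a proportional-hazards model is fitted per pair and scored
by Harrell's C on the fitting data.  Controls are equal-sized sets of gene
pairs drawn by one of four strategies; for every repetition a fresh
control draw is fitted identically and a one-sided Mann-Whitney test asks
whether the dysregulation C-indexes are larger.  The median of the
repeated p-values summarizes each (model type, strategy) cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .containers import ExpressionMatrix, ReferenceGRN
from .coxmodel import fit_cox

CLINICAL_COVARIATES = ["age", "gender", "stage"]

STRATEGIES = ("random_pair", "deg_nondeg_pair", "refgrn_edge", "refgrn_edge_deg_target")


@dataclass
class ModelType:
    endpoint: str                 # "os" or "rfs"
    with_clinical: bool

    @property
    def key(self) -> str:
        return ("Exp+Clin_" if self.with_clinical else "Exp_") + self.endpoint.upper()


MODEL_TYPES = [ModelType("os", True), ModelType("os", False),
               ModelType("rfs", True), ModelType("rfs", False)]


@dataclass
class ScreenResult:
    pvalues: dict = field(default_factory=dict)   # (model_key, strategy) -> list[float]
    medians: dict = field(default_factory=dict)
    n_dysregs: int = 0
    skipped: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"n_dysregs": self.n_dysregs,
                "medians": {f"{mk}|{st}": v for (mk, st), v in self.medians.items()},
                "pvalues": {f"{mk}|{st}": v for (mk, st), v in self.pvalues.items()},
                "skipped": self.skipped}


def sample_controls(strategy: str, n_pairs: int, gene_pool: list[str],
                    deg_set: set[str], refgrn: ReferenceGRN,
                    rng: np.random.Generator) -> list[tuple[str, str]]:
    """Draw n_pairs control gene pairs without replacement.

    random_pair: two genes from the preprocessed gene list;
    deg_nondeg_pair: one DEG plus one non-DEG; refgrn_edge: a reference-
    network edge; refgrn_edge_deg_target: an edge whose target is a DEG.
    """
    if strategy == "random_pair":
        if len(gene_pool) < 2 * n_pairs:
            raise ValueError("gene pool too small for requested pairs")
        picks = rng.choice(len(gene_pool), size=2 * n_pairs, replace=False)
        return [(gene_pool[picks[2 * i]], gene_pool[picks[2 * i + 1]])
                for i in range(n_pairs)]
    if strategy == "deg_nondeg_pair":
        degs = sorted(set(gene_pool) & deg_set)
        nondegs = sorted(set(gene_pool) - deg_set)
        if len(degs) < n_pairs or len(nondegs) < n_pairs:
            raise ValueError("not enough DEGs / non-DEGs for requested pairs")
        di = rng.choice(len(degs), size=n_pairs, replace=False)
        ni = rng.choice(len(nondegs), size=n_pairs, replace=False)
        return [(degs[a], nondegs[b]) for a, b in zip(di, ni)]
    if strategy in ("refgrn_edge", "refgrn_edge_deg_target"):
        edges = refgrn.edges
        if strategy == "refgrn_edge_deg_target":
            edges = edges[edges["target"].isin(deg_set)]
        pairs = list(zip(edges["tf"], edges["target"]))
        if len(pairs) < n_pairs:
            raise ValueError(f"only {len(pairs)} edges available for {strategy}")
        idx = rng.choice(len(pairs), size=n_pairs, replace=False)
        return [pairs[i] for i in idx]
    raise ValueError(f"unknown control strategy {strategy!r}")


def _pair_cindex(pair: tuple[str, str], values: pd.DataFrame, clin: pd.DataFrame,
                 mt: ModelType) -> float | None:
    """C-index of one gene pair under one model type; None if the pair is
    unusable or the fit does not converge."""
    g1, g2 = pair
    if g1 not in values.index or g2 not in values.index:
        return None
    cols = [values.loc[g1].to_numpy(), values.loc[g2].to_numpy()]
    if mt.with_clinical:
        cols += [clin[c].to_numpy(dtype=float) for c in CLINICAL_COVARIATES]
    Z = np.column_stack(cols)
    if (Z.std(axis=0) == 0).any():
        return None
    times = clin[f"{mt.endpoint}_time"].to_numpy(dtype=float)
    events = clin[f"{mt.endpoint}_event"].to_numpy(dtype=float).astype(int)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_cox(Z, times, events)
    except (ValueError, np.linalg.LinAlgError):
        return None
    return fit.c_index if fit.converged else None


def available_model_types(clinical: pd.DataFrame) -> list[ModelType]:
    """OS models always; RFS models only when rfs columns are usable."""
    out = [mt for mt in MODEL_TYPES if mt.endpoint == "os"]
    if {"rfs_time", "rfs_event"}.issubset(clinical.columns) and \
            clinical["rfs_time"].notna().all():
        out += [mt for mt in MODEL_TYPES if mt.endpoint == "rfs"]
    return out


def prognostic_screen(dysreg_pairs: list[tuple[str, str]], expr: ExpressionMatrix,
                      clinical: pd.DataFrame, refgrn: ReferenceGRN,
                      deg_set: set[str], n_reps: int = 100, seed: int = 0,
                      strategies: tuple[str, ...] = STRATEGIES,
                      min_fits: int = 10) -> ScreenResult:
    """Run the full screen: dysregulation C-indexes vs repeated controls.

    The dysregulation arm is fitted once per model type; every repetition
    redraws each control arm and reruns the one-sided Mann-Whitney test
    (dysregulations > controls).  Repetitions with fewer than ``min_fits``
    successful fits in either arm are skipped and logged.
    """
    if not dysreg_pairs:
        raise ValueError("no dysregulations to screen")
    samples = [s for s in clinical.index if s in set(expr.samples)]
    if not samples:
        raise ValueError("no overlap between clinical table and expression samples")
    clin = clinical.loc[samples]
    values = expr.values[samples]
    gene_pool = sorted(values.index)
    model_types = available_model_types(clin)
    rng = np.random.default_rng(seed)
    result = ScreenResult(n_dysregs=len(dysreg_pairs))
    dys_c: dict[str, list[float]] = {}
    for mt in model_types:
        cs = [_pair_cindex(p, values, clin, mt) for p in dysreg_pairs]
        dys_c[mt.key] = [c for c in cs if c is not None]
    for mt in model_types:
        for st in strategies:
            result.pvalues[(mt.key, st)] = []
    for rep in range(n_reps):
        for st in strategies:
            pairs = sample_controls(st, len(dysreg_pairs), gene_pool, deg_set,
                                    refgrn, rng)
            for mt in model_types:
                ctrl = [_pair_cindex(p, values, clin, mt) for p in pairs]
                ctrl = [c for c in ctrl if c is not None]
                if len(ctrl) < min_fits or len(dys_c[mt.key]) < min_fits:
                    result.skipped.append({"rep": rep, "model": mt.key,
                                           "strategy": st,
                                           "n_ctrl_fits": len(ctrl)})
                    continue
                p = mannwhitneyu(dys_c[mt.key], ctrl, alternative="greater").pvalue
                result.pvalues[(mt.key, st)].append(float(p))
    for key, ps in result.pvalues.items():
        result.medians[key] = float(np.median(ps)) if ps else float("nan")
    return result
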