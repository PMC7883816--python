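"""Dysregulation calling: moderated differential expression of targets and
integration of the three criteria.

A TF->target link is called dysregulated when (i) the 95% confidence
intervals of its regulatory intensity in the two conditions are disjoint,
(ii) the target is differentially expressed (|log2 fold change| above the
cutoff with BH-adjusted moderated-t p below the cutoff), and (iii) the
intensity change and the target's expression change point the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, NORMAL, TUMOR


@dataclass
class EBayesHyperparams:
    """Empirical-Bayes variance prior: d0 prior degrees of freedom (may be
    inf) and s0sq prior variance."""
    d0: float
    s0sq: float


@dataclass
class DEGResult:
    gene: str
    logFC: float
    s2: float
    t_mod: float
    p: float
    p_adj: float
    is_deg: bool
    direction: str


@dataclass
class Dysregulation:
    tf: str
    target: str
    beta_normal: float
    ci_normal: tuple[float, float]
    beta_tumor: float
    ci_tumor: tuple[float, float]
    delta_beta: float
    target_logFC: float
    target_p_adj: float
    consistent: bool = True


def _fit_variance_prior(s2: np.ndarray, d: float) -> EBayesHyperparams:
    """Moment matching on log s^2 (Smyth's scheme): E[log s2] and
    Var[log s2] identify (d0, s0^2) through digamma/trigamma."""
    s2 = np.maximum(s2, 1e-300)
    e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
    e_var = np.var(e, ddof=1) if len(e) > 1 else 0.0
    target_var = e_var - float(special.polygamma(1, d / 2))
    if target_var <= 1e-8:
        return EBayesHyperparams(d0=np.inf, s0sq=float(np.exp(np.mean(e))))
    # invert trigamma(d0/2) = target_var by Newton on x = d0/2
    x = 0.5 + 1.0 / target_var          # standard starting point
    for _ in range(60):
        tri = float(special.polygamma(1, x))
        step = tri * (tri / target_var - 1.0) / float(special.polygamma(2, x))
        x = max(x - step, 1e-8)
        if abs(step) < 1e-10 * x:
            break
    d0 = 2 * x
    s0sq = float(np.exp(np.mean(e) + special.digamma(x) - np.log(x)))
    return EBayesHyperparams(d0=d0, s0sq=s0sq)


def moderated_t_test(expr: ExpressionMatrix, lfc_threshold: float = 1.0,
                     p_threshold: float = 0.05, paired: bool = False,
                     d0_override: float | None = None) -> list[DEGResult]:
    """limma-style moderated t test of tumor vs normal per gene.

    Gene variances are shrunk toward an empirical-Bayes prior fitted to
    all genes; the moderated t has d0 + d degrees of freedom.  BH
    adjustment runs across all tested genes.  ``d0_override=0`` turns
    shrinkage off (ordinary t).
    """
    normal = expr.subset_condition(NORMAL).values
    tumor = expr.subset_condition(TUMOR).values
    genes = list(expr.genes)
    if paired:
        if not expr.pairing:
            raise ValueError("paired test requested but no pairing available")
        pairs = [(t, n) for t, n in expr.pairing.items()
                 if t in tumor.columns and n in normal.columns]
        if len(pairs) < 3:
            raise ValueError("need >= 3 pairs")
        diff = (tumor[[t for t, _ in pairs]].to_numpy()
                - normal[[n for _, n in pairs]].to_numpy())
        logfc = diff.mean(axis=1)
        d = diff.shape[1] - 1
        s2 = diff.var(axis=1, ddof=1)
        v = 1.0 / diff.shape[1]
    else:
        n1, n2 = normal.shape[1], tumor.shape[1]
        if min(n1, n2) < 3:
            raise ValueError("need >= 3 samples per group")
        a = normal.to_numpy()
        b = tumor.to_numpy()
        logfc = b.mean(axis=1) - a.mean(axis=1)
        d = n1 + n2 - 2
        s2 = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        s2 += ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        s2 /= d
        v = 1.0 / n1 + 1.0 / n2
    zero_var = s2 <= 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance genes; variance floored")
        s2 = np.maximum(s2, np.finfo(float).eps)
    if d0_override is not None:
        prior = EBayesHyperparams(d0=float(d0_override),
                                  s0sq=float(np.median(s2)))
    else:
        prior = _fit_variance_prior(s2, d)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0sq)
        df_total = 1e9
    else:
        s2_post = (prior.d0 * prior.s0sq + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d
    t_mod = logfc / np.sqrt(s2_post * v)
    p = 2 * stats.t.sf(np.abs(t_mod), df_total)
    p_adj = multipletests(p, method="fdr_bh")[1]
    out = []
    for i, g in enumerate(genes):
        is_deg = bool(abs(logfc[i]) > lfc_threshold and p_adj[i] < p_threshold)
        out.append(DEGResult(gene=g, logFC=float(logfc[i]), s2=float(s2[i]),
                             t_mod=float(t_mod[i]), p=float(p[i]),
                             p_adj=float(p_adj[i]), is_deg=is_deg,
                             direction="up" if logfc[i] >= 0 else "down"))
    return out


def ci_disjoint(ci_a: tuple[float, float], ci_b: tuple[float, float]) -> bool:
    """Strictly disjoint intervals; touching endpoints count as overlap."""
    return ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0]


def direction_consistent(delta_beta: float, target_logFC: float) -> bool:
    """Intensity change and expression change share a (nonzero) sign."""
    return delta_beta * target_logFC > 0


def identify_dysregulations(intensities: pd.DataFrame, degs: list[DEGResult]
                            ) -> list[Dysregulation]:
    """Integrate the three criteria over a both-condition intensity table.

    ``intensities`` is the tidy frame from estimate_intensities.  Links
    whose target has no DEG record are skipped with a warning.  Output is
    ordered by |delta beta| descending.
    """
    deg_by_gene = {d.gene: d for d in degs}
    out: list[Dysregulation] = []
    wide = intensities.pivot_table(index=["target", "tf"], columns="condition",
                                   values=["beta_hat", "ci_low", "ci_high"],
                                   aggfunc="first")
    for (target, tf), row in wide.iterrows():
        try:
            bn = float(row[("beta_hat", NORMAL)])
            bt = float(row[("beta_hat", TUMOR)])
            cin = (float(row[("ci_low", NORMAL)]), float(row[("ci_high", NORMAL)]))
            cit = (float(row[("ci_low", TUMOR)]), float(row[("ci_high", TUMOR)]))
        except KeyError:
            continue
        if np.isnan(bn) or np.isnan(bt):
            continue
        deg = deg_by_gene.get(target)
        if deg is None:
            warnings.warn(f"target {target} missing from DEG table; link skipped")
            continue
        if not deg.is_deg:
            continue
        if not ci_disjoint(cin, cit):
            continue
        delta = bt - bn
        if not direction_consistent(delta, deg.logFC):
            continue
        out.append(Dysregulation(tf=tf, target=target, beta_normal=bn,
                                 ci_normal=cin, beta_tumor=bt, ci_tumor=cit,
                                 delta_beta=delta, target_logFC=deg.logFC,
                                 target_p_adj=deg.p_adj))
    out.sort(key=lambda z: (-abs(z.delta_beta), z.target, z.tf))
    return out


def degs_to_frame(degs: list[DEGResult]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in degs])


def dysregs_to_frame(dys: list[Dysregulation]) -> pd.DataFrame:
    rows = []
    for z in dys:
        rows.append({"tf": z.tf, "target": z.target,
                     "beta_normal": z.beta_normal,
                     "ci_n_lo": z.ci_normal[0], "ci_n_hi": z.ci_normal[1],
                     "beta_tumor": z.beta_tumor,
                     "ci_t_lo": z.ci_tumor[0], "ci_t_hi": z.ci_tumor[1],
                     "delta_beta": z.delta_beta,
                     "logFC": z.target_logFC, "p_adj": z.target_p_adj})
    return pd.DataFrame(rows, columns=["tf", "target", "beta_normal", "ci_n_lo",
                                       "ci_n_hi", "beta_tumor", "ci_t_lo", "ci_t_hi",
                                       "delta_beta", "logFC", "p_adj"])


def frame_to_dysregs(df: pd.DataFrame) -> list[Dysregulation]:
    out = []
    for _, r in df.iterrows():
        out.append(Dysregulation(
            tf=r["tf"], target=r["target"], beta_normal=float(r["beta_normal"]),
            ci_normal=(float(r["ci_n_lo"]), float(r["ci_n_hi"])),
            beta_tumor=float(r["beta_tumor"]),
            ci_tumor=(float(r["ci_t_lo"]), float(r["ci_t_hi"])),
            delta_beta=float(r["delta_beta"]), target_logFC=float(r["logFC"]),
            target_p_adj=float(r["p_adj"])))
    return out
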