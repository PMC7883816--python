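"""Dysregulation signature: greedy forward selection under repeated-split
cross-validation, risk scoring, survival evaluation, and the
treatment-benefit transfer analysis.

The primary dysregulation is the one whose full-data OS model (two genes
plus clinical covariates) has the largest C-index.  Each greedy iteration
evaluates every remaining candidate by adding its genes and scoring the
enlarged model with repeated 60/40 train/test splits (median test
C-index, splits shared across candidates within an iteration); the best
candidate joins while the improvement is at least ``delta_c_stop``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from .containers import ExpressionMatrix
from .coxmodel import CoxFit, concordance_index, fit_cox
from .survscreen import CLINICAL_COVARIATES


@dataclass
class GreedyConfig:
    train_frac: float = 0.6
    n_reps: int = 100
    delta_c_stop: float = 0.001
    seed: int = 0
    restrict_genes: set[str] | None = None   # keep candidates with >=1 gene in set

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.delta_c_stop <= 0:
            raise ValueError("delta_c_stop must be positive")


@dataclass
class SignatureModel:
    dysregulations: list[tuple[str, str]]
    genes: list[str]
    clinical: list[str]
    coef: dict[str, float]
    c_index_history: list[float]
    full_c_index: float | None = None


@dataclass
class RiskScoreResult:
    scores: pd.Series
    grouping: str                           # "median" or "sign"
    groups: pd.Series                       # "high"/"low" or "positive"/"negative"
    threshold: float


@dataclass
class TimeAUC:
    eval_times: list[float]
    auc: list[float]
    censoring_model: str = "Kaplan-Meier on the censoring indicator"


@dataclass
class KMComparison:
    curves: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float | None
    hr_ci: tuple[float, float] | None
    group_sizes: dict[str, int] = field(default_factory=dict)


def _design(genes: list[str], clinical_cols: list[str], expr_values: pd.DataFrame,
            clin: pd.DataFrame, samples: list[str]) -> np.ndarray:
    cols = [expr_values.loc[g, samples].to_numpy(dtype=float) for g in genes]
    cols += [clin.loc[samples, c].to_numpy(dtype=float) for c in clinical_cols]
    return np.column_stack(cols)


def _dedup_genes(pairs: list[tuple[str, str]]) -> list[str]:
    seen: list[str] = []
    for tf, tg in pairs:
        for g in (tf, tg):
            if g not in seen:
                seen.append(g)
    return seen


def _cv_median_cindex(genes: list[str], clinical_cols: list[str],
                      values: pd.DataFrame, clin: pd.DataFrame,
                      samples: list[str], splits: list[np.ndarray]) -> float:
    """Median test C-index over pre-drawn train index sets."""
    Z = _design(genes, clinical_cols, values, clin, samples)
    times = clin.loc[samples, "os_time"].to_numpy(dtype=float)
    events = clin.loc[samples, "os_event"].to_numpy(dtype=float).astype(int)
    n = len(samples)
    cs = []
    for train_idx in splits:
        mask = np.zeros(n, dtype=bool)
        mask[train_idx] = True
        if events[mask].sum() < 5 or events[~mask].sum() < 2:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_cox(Z[mask], times[mask], events[mask])
            if not fit.converged:
                continue
            lp = fit.linear_predictor(Z[~mask])
            cs.append(concordance_index(lp, times[~mask], events[~mask]))
        except (ValueError, np.linalg.LinAlgError):
            continue
    return float(np.median(cs)) if cs else float("nan")


def greedy_build(candidates: list[tuple[str, str]], expr: ExpressionMatrix,
                 clinical: pd.DataFrame, cfg: GreedyConfig | None = None
                 ) -> SignatureModel:
    """Greedy forward selection of dysregulations for an OS signature.

    ``candidates`` are (tf, target) pairs.  The primary is chosen by
    full-data C-index; growth is scored by repeated-split CV with split
    seeds shared across candidates within an iteration.
    """
    cfg = cfg or GreedyConfig()
    samples = [s for s in clinical.index if s in set(expr.samples)]
    clin = clinical.loc[samples]
    values = expr.values
    genes_avail = set(values.index)
    cand = [c for c in candidates if c[0] in genes_avail and c[1] in genes_avail]
    if cfg.restrict_genes is not None:
        cand = [c for c in cand if c[0] in cfg.restrict_genes
                or c[1] in cfg.restrict_genes]
    if not cand:
        raise ValueError("no usable candidates")
    times = clin["os_time"].to_numpy(dtype=float)
    events = clin["os_event"].to_numpy(dtype=float).astype(int)

    # primary: largest full-data C-index (two genes + clinical)
    best_primary, best_c = None, -np.inf
    for pair in cand:
        Z = _design(_dedup_genes([pair]), CLINICAL_COVARIATES, values, clin, samples)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_cox(Z, times, events)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if fit.converged and fit.c_index is not None and fit.c_index > best_c:
            best_primary, best_c = pair, fit.c_index
    if best_primary is None:
        raise ValueError("no candidate model converged")

    included = [best_primary]
    remaining = [c for c in cand if c != best_primary]
    rng = np.random.default_rng(cfg.seed)
    n = len(samples)
    n_train = max(2, int(round(cfg.train_frac * n)))

    def draw_splits() -> list[np.ndarray]:
        return [rng.permutation(n)[:n_train] for _ in range(cfg.n_reps)]

    history = [_cv_median_cindex(_dedup_genes(included), CLINICAL_COVARIATES,
                                 values, clin, samples, draw_splits())]
    while remaining:
        splits = draw_splits()               # shared across candidates (paired)
        scores = []
        for pair in remaining:
            genes = _dedup_genes(included + [pair])
            scores.append(_cv_median_cindex(genes, CLINICAL_COVARIATES, values,
                                            clin, samples, splits))
        best_i = int(np.nanargmax(scores))
        if not np.isfinite(scores[best_i]) or \
                scores[best_i] < history[-1] + cfg.delta_c_stop:
            break
        included.append(remaining.pop(best_i))
        history.append(scores[best_i])

    genes = _dedup_genes(included)
    Z = _design(genes, CLINICAL_COVARIATES, values, clin, samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_cox(Z, times, events,
                      covariates=genes + CLINICAL_COVARIATES)
    coef = dict(zip(fit.covariates, fit.coef))
    return SignatureModel(dysregulations=included, genes=genes,
                          clinical=list(CLINICAL_COVARIATES), coef=coef,
                          c_index_history=history, full_c_index=fit.c_index)


def risk_score(fit: CoxFit, genes: list[str], clinical_cols: list[str],
               expr: ExpressionMatrix, clinical: pd.DataFrame,
               grouping: str = "median") -> RiskScoreResult:
    """Score samples with a fitted model's linear predictor (centered at
    the training covariate means) and split into two groups.

    grouping="median": high/low by cohort median, ties going to low.
    grouping="sign": positive (> 0) vs negative (<= 0).
    """
    missing = [g for g in genes if g not in set(expr.genes)]
    if missing:
        raise ValueError(f"genes missing from expression: {missing}")
    samples = [s for s in clinical.index if s in set(expr.samples)]
    Z = _design(genes, clinical_cols, expr.values, clinical, samples)
    scores = pd.Series(fit.linear_predictor(Z), index=samples, name="risk_score")
    if grouping == "median":
        thr = float(scores.median())
        groups = pd.Series(np.where(scores > thr, "high", "low"), index=samples)
    elif grouping == "sign":
        thr = 0.0
        groups = pd.Series(np.where(scores > 0, "positive", "negative"), index=samples)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return RiskScoreResult(scores=scores, grouping=grouping, groups=groups,
                           threshold=thr)


def km_logrank_hr(groups: pd.Series, times: pd.Series, events: pd.Series,
                  numerator: str | None = None) -> KMComparison:
    """Kaplan-Meier curves, log-rank test and the hazard ratio between two
    groups.

    ``numerator`` names the group whose hazard goes in the HR numerator;
    by default the "low" (median split) or "negative" (sign split) group,
    so a protective split reports HR < 1.
    """
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float).astype(int)
    g = np.asarray(groups)
    curves = {}
    sizes = {}
    for lab in labels:
        m = g == lab
        curves[lab] = _km_curve(t[m], e[m])
        sizes[lab] = int(m.sum())
    lr = logrank_test(t[g == labels[0]], t[g == labels[1]],
                      e[g == labels[0]], e[g == labels[1]])
    hr = hr_ci = None
    if numerator is None:
        preferred = [l for l in ("low", "negative") if l in labels]
        numerator = preferred[0] if preferred else labels[1]
    if all(e[g == lab].sum() > 0 for lab in labels[:2]):
        ind = (g == numerator).astype(float)[:, None]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_cox(ind, t, e, covariates=["group"])
            if fit.converged:
                hr = float(np.exp(fit.coef[0]))
                se = fit.se[0]
                hr_ci = (float(np.exp(fit.coef[0] - 1.96 * se)),
                         float(np.exp(fit.coef[0] + 1.96 * se)))
        except (ValueError, np.linalg.LinAlgError):
            pass
    else:
        warnings.warn("a group has zero events; hazard ratio undefined")
    return KMComparison(curves=curves, logrank_chi2=float(lr.test_statistic),
                        logrank_p=float(lr.p_value), hazard_ratio=hr,
                        hr_ci=hr_ci, group_sizes=sizes)


def _km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit estimate as a step table (time, at_risk, events, S)."""
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq = np.unique(t[e == 1])
    rows = []
    s = 1.0
    for u in uniq:
        at_risk = int((t >= u).sum())
        d = int(((t == u) & (e == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append((float(u), at_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def _censoring_survival_left(times: np.ndarray, events: np.ndarray,
                             at: np.ndarray) -> np.ndarray:
    """Left-continuous KM of the censoring distribution evaluated at
    ``at``: G(t-) = prod over censoring times u < t of (1 - dc(u)/Y(u))."""
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    cens_times = np.unique(t[e == 0])
    factors = []
    for u in cens_times:
        y = (t >= u).sum()
        dc = ((t == u) & (e == 0)).sum()
        factors.append((u, 1.0 - dc / y))
    out = np.ones(len(at))
    for i, a in enumerate(at):
        g = 1.0
        for u, f in factors:
            if u < a:
                g *= f
        out[i] = g
    return out


def time_dependent_auc(scores, times, events, eval_times) -> TimeAUC:
    """IPCW cumulative/dynamic AUC(t).

    Cases at t: event observed by t, weighted by 1/G(T-) where G is the
    Kaplan-Meier censoring survival; controls: still at risk beyond t.
    With no censoring all weights are one and AUC(t) is the empirical
    binary AUC of event-by-t, exactly.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float).astype(int)
    aucs = []
    Gmin = _censoring_survival_left(t, e, t)
    for tau in eval_times:
        cases = (t <= tau) & (e == 1)
        controls = t > tau
        if cases.sum() == 0 or controls.sum() == 0:
            warnings.warn(f"no cases or controls at t={tau}; AUC missing")
            aucs.append(float("nan"))
            continue
        w = 1.0 / np.maximum(Gmin[cases], 1e-12)
        sc = s[cases][:, None]
        sn = s[controls][None, :]
        wins = (sc > sn) + 0.5 * (sc == sn)
        num = float((w[:, None] * wins).sum())
        den = float(w.sum() * controls.sum())
        aucs.append(num / den)
    return TimeAUC(eval_times=list(eval_times), auc=aucs)


def cross_validate_signature(genes: list[str], expr: ExpressionMatrix,
                             clinical: pd.DataFrame, cfg: GreedyConfig | None = None,
                             eval_times=(1.0, 3.0, 5.0),
                             clinical_cols: list[str] | None = None) -> pd.DataFrame:
    """Repeated 60/40 cross-validation of a fixed gene signature.

    Per repetition: fit genes + clinical on the training split; on the
    test split compute train/test C-index, AUC at the evaluation times,
    and the log-rank p of the median risk-score split.  Returns one row
    per successful repetition; summarize with .median()/.quantile().
    """
    cfg = cfg or GreedyConfig()
    clinical_cols = CLINICAL_COVARIATES if clinical_cols is None else clinical_cols
    samples = [s for s in clinical.index if s in set(expr.samples)]
    clin = clinical.loc[samples]
    Z = _design(genes, clinical_cols, expr.values, clin, samples)
    times = clin["os_time"].to_numpy(dtype=float)
    events = clin["os_event"].to_numpy(dtype=float).astype(int)
    n = len(samples)
    n_train = max(2, int(round(cfg.train_frac * n)))
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rep in range(cfg.n_reps):
        idx = rng.permutation(n)
        tr, te = idx[:n_train], idx[n_train:]
        if events[tr].sum() < 5 or events[te].sum() < 2:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_cox(Z[tr], times[tr], events[tr])
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not fit.converged:
            continue
        lp_te = fit.linear_predictor(Z[te])
        try:
            c_te = concordance_index(lp_te, times[te], events[te])
        except ValueError:
            continue
        auc = time_dependent_auc(lp_te, times[te], events[te], eval_times).auc
        med = np.median(lp_te)
        grp = np.where(lp_te > med, "high", "low")
        if len(np.unique(grp)) == 2 and all(events[te][grp == x].sum() > 0
                                            for x in ("high", "low")):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lr = logrank_test(times[te][grp == "high"], times[te][grp == "low"],
                                  events[te][grp == "high"], events[te][grp == "low"])
            neglogp = float(-np.log10(max(lr.p_value, 1e-300)))
        else:
            neglogp = float("nan")
        row = {"rep": rep, "c_index_train": fit.c_index, "c_index_test": c_te,
               "neg_log10_logrank_p": neglogp}
        for tau, a in zip(eval_times, auc):
            row[f"auc_{tau:g}"] = a
        rows.append(row)
    return pd.DataFrame(rows)


def benefit_transfer(genes: list[str], expr: ExpressionMatrix,
                     clinical: pd.DataFrame, adjc_type: str | None = None,
                     eval_times=(1.0, 3.0, 5.0)
                     ) -> tuple[KMComparison, TimeAUC, RiskScoreResult]:
    """Train an OS model on untreated samples (genes only) and evaluate
    the sign-of-score split among treated samples.

    Returns the KM/log-rank/HR comparison between negative- and
    positive-score treated patients, the IPCW AUC of the transferred score
    among treated patients, and the scores themselves.
    """
    if "adjc" not in clinical.columns:
        raise ValueError("clinical table lacks the adjc flag")
    untreated = clinical[clinical["adjc"] == 0]
    treated = clinical[clinical["adjc"] == 1]
    if adjc_type is not None:
        treated = treated[treated["adjc_type"] == adjc_type]
    if len(untreated) == 0:
        raise ValueError("no untreated samples to train on")
    if len(treated) == 0:
        raise ValueError("no treated samples to score")
    u_samples = [s for s in untreated.index if s in set(expr.samples)]
    Zu = _design(genes, [], expr.values, clinical, u_samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_cox(Zu, untreated.loc[u_samples, "os_time"].to_numpy(dtype=float),
                      untreated.loc[u_samples, "os_event"].to_numpy(dtype=float).astype(int),
                      covariates=genes)
    rs = risk_score(fit, genes, [], expr, treated, grouping="sign")
    if rs.groups.nunique() < 2:
        warnings.warn("all treated scores share one sign; comparison degenerate")
        km = KMComparison(curves={}, logrank_chi2=float("nan"),
                          logrank_p=float("nan"), hazard_ratio=None, hr_ci=None)
    else:
        km = km_logrank_hr(rs.groups, treated.loc[rs.scores.index, "os_time"],
                           treated.loc[rs.scores.index, "os_event"])
    auc = time_dependent_auc(rs.scores.to_numpy(),
                             treated.loc[rs.scores.index, "os_time"].to_numpy(dtype=float),
                             treated.loc[rs.scores.index, "os_event"].to_numpy(dtype=float),
                             eval_times)
    return km, auc, rs
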