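"""Condition-specific network pruning by shadow-feature selection.

For each target gene, its candidate TFs (from the reference network) are
the features of a regression random forest predicting the target's
expression in one condition.  Every round, a permuted ("shadow") copy of
each still-active feature is appended; a feature scores a hit when its
importance exceeds the round's maximum shadow importance.  A Bonferroni-
corrected two-sided binomial test on the hit counts confirms features with
significantly many hits and rejects those with significantly few.  Links
whose TF is confirmed survive into the conditional network.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom
from sklearn.ensemble import RandomForestRegressor

from .containers import ConditionalGRN, ExpressionMatrix, ReferenceGRN

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"


@dataclass
class SelectionDecision:
    tf: str
    status: str
    hit_count: int
    n_rounds: int
    importance_z: float = float("nan")


@dataclass
class ShadowSelectConfig:
    """Knobs of the shadow-selection loop.

    n_trees per forest (impurity importance), max_rounds, the two-sided
    binomial alpha (Bonferroni-corrected across undecided features), the
    policy for features still undecided at termination, and the seed.
    """

    n_trees: int = 150
    max_rounds: int = 100
    alpha: float = 0.05
    seed: int = 0
    tentative_policy: str = "drop"          # or "keep_if_above_median_shadow"
    max_features: str | float = "sqrt"
    min_samples_leaf: int = 5
    min_samples: int = 8
    _extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_rounds < 10:
            raise ValueError("max_rounds must be >= 10")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.tentative_policy not in ("drop", "keep_if_above_median_shadow"):
            raise ValueError(f"unknown tentative_policy {self.tentative_policy!r}")


def _target_seed(global_seed: int, target: str) -> int:
    """Stable per-target seed so per-target runs are order-independent."""
    return (int(global_seed) * 1000003 + zlib.crc32(target.encode())) % (2**31 - 1)


def shadow_select(X: np.ndarray, y: np.ndarray, cfg: ShadowSelectConfig | None = None,
                  feature_names: list[str] | None = None) -> list[SelectionDecision]:
    """Run the iterative shadow-feature selection on one regression problem.

    X: samples x candidate-TF expression; y: target expression.  Returns a
    decision per feature.  Deterministic given cfg.seed.
    """
    cfg = cfg or ShadowSelectConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < cfg.min_samples:
        raise ValueError(f"need >= {cfg.min_samples} samples, got {n}")
    if p < 1:
        raise ValueError("need >= 1 candidate feature")
    if y.shape[0] != n:
        raise ValueError("y not aligned with X rows")
    names = feature_names if feature_names is not None else [f"x{j}" for j in range(p)]
    rng = np.random.default_rng(cfg.seed)

    status = np.full(p, TENTATIVE, dtype=object)
    hits = np.zeros(p, dtype=int)
    const_cols = X.std(axis=0) == 0
    status[const_cols] = REJECTED
    if np.std(y) == 0:
        warnings.warn("constant response: all features rejected")
        return [SelectionDecision(names[j], REJECTED, 0, 0) for j in range(p)]

    n_rounds = 0
    last_z = np.full(p, np.nan)
    for _ in range(cfg.max_rounds):
        active = np.where(status != REJECTED)[0]
        undecided = np.where(status == TENTATIVE)[0]
        if len(undecided) == 0 or len(active) == 0:
            break
        n_rounds += 1
        Xa = X[:, active]
        # shadow pool padded to the original feature count: as features get
        # rejected the pool would otherwise shrink and its maximum collapse,
        # letting chance-correlated survivors rack up hits
        n_shadow = max(5, p)
        shadows = np.empty((n, n_shadow))
        for j in range(n_shadow):
            shadows[:, j] = X[:, active[j % len(active)]]
            rng.shuffle(shadows[:, j])
        Xaug = np.hstack([Xa, shadows])
        forest = RandomForestRegressor(
            n_estimators=cfg.n_trees, max_features=cfg.max_features,
            min_samples_leaf=cfg.min_samples_leaf,
            random_state=int(rng.integers(2**31 - 1)), n_jobs=1, **cfg._extra)
        forest.fit(Xaug, y)
        imp = forest.feature_importances_
        real_imp = imp[:len(active)]
        shadow_imp = imp[len(active):]
        shadow_max = shadow_imp.max() if len(shadow_imp) else 0.0
        shadow_sd = shadow_imp.std() if len(shadow_imp) > 1 else 0.0
        hits[active[real_imp > shadow_max]] += 1
        if shadow_sd > 0:
            last_z[active] = (real_imp - shadow_imp.mean()) / shadow_sd
        # Bonferroni-corrected two-sided binomial decisions (across all features)
        thr = cfg.alpha / (2.0 * p)
        for j in undecided:
            p_hi = binom.sf(hits[j] - 1, n_rounds, 0.5)
            p_lo = binom.cdf(hits[j], n_rounds, 0.5)
            if p_hi < thr:
                status[j] = CONFIRMED
            elif p_lo < thr:
                status[j] = REJECTED
    return [SelectionDecision(names[j], str(status[j]), int(hits[j]), n_rounds,
                              float(last_z[j])) for j in range(p)]


def build_conditional_grn(expr: ExpressionMatrix, refgrn: ReferenceGRN,
                          cfg: ShadowSelectConfig | None = None,
                          condition: str | None = None
                          ) -> tuple[ConditionalGRN, dict[str, list[SelectionDecision]]]:
    """Prune the reference network using one condition's expression.

    ``expr`` must already be restricted to one condition (or pass
    ``condition`` to restrict here).  Runs shadow_select once per target
    over its candidate TFs; per-target seeds derive from (cfg.seed,
    target), so results are independent of target order.
    """
    cfg = cfg or ShadowSelectConfig()
    if condition is not None:
        expr = expr.subset_condition(condition)
        label = condition
    else:
        conds = set(expr.condition[expr.samples])
        label = conds.pop() if len(conds) == 1 else "mixed"
    n = len(expr.samples)
    if n < 20:
        warnings.warn(f"only {n} samples in condition '{label}'; selection may be unstable")
    genes = set(expr.genes)
    values = expr.values
    edges: dict[str, set[str]] = {}
    log: dict[str, list[SelectionDecision]] = {}
    targets = sorted(set(refgrn.edges["target"]))
    for target in targets:
        if target not in genes:
            warnings.warn(f"target {target} absent from expression; skipped")
            continue
        tfs = [tf for tf in refgrn.candidate_tfs(target) if tf in genes and tf != target]
        if not tfs:
            continue
        X = values.loc[tfs].to_numpy().T
        y = values.loc[target].to_numpy()
        tcfg = ShadowSelectConfig(
            n_trees=cfg.n_trees, max_rounds=cfg.max_rounds, alpha=cfg.alpha,
            seed=_target_seed(cfg.seed, target), tentative_policy=cfg.tentative_policy,
            max_features=cfg.max_features, min_samples_leaf=cfg.min_samples_leaf,
            min_samples=cfg.min_samples, _extra=cfg._extra)
        decisions = shadow_select(X, y, tcfg, feature_names=tfs)
        log[target] = decisions
        keep = {d.tf for d in decisions if d.status == CONFIRMED}
        if cfg.tentative_policy == "keep_if_above_median_shadow":
            keep |= {d.tf for d in decisions
                     if d.status == TENTATIVE and d.importance_z > 0}
        if keep:
            edges[target] = keep
    grn = ConditionalGRN(condition=label, edges=edges)
    grn.assert_subset_of(refgrn)
    return grn, log
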