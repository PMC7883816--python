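"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator plants a TF->target network with linear condition-specific
regulation, a chosen fraction of dysregulated links (intensity change
paired with a consistent intercept shift so the target is differentially
expressed in the matching direction), survival times whose log-hazard is
linear in a subset of genes, independent censoring calibrated to a target
rate, and a treated/untreated split.  Every stage of the pipeline can be
scored against the planted truth.

Defaults mirror the study conditions the pipeline targets: 32 matched
normal/tumor pairs for dysregulation discovery, a ~300-sample tumor
cohort for survival, TF expression centered at a positive mean
(``tf_mean``=2) so that an intensity increase raises the target mean, and
exponential event times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, NORMAL, TUMOR, ReferenceGRN
from . import io as dio


@dataclass
class SyntheticTruth:
    tfs: list[str]
    targets: list[str]
    links: pd.DataFrame          # tf, target, beta_normal, beta_tumor, dysregulated
    intercepts: pd.DataFrame     # target, normal, tumor
    deg_flags: dict[str, bool]
    tf_mean: float
    effect_size: float
    hazard_coefs: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.1
    censor_rate: float = 0.3
    treatment_benefit: float = 0.0

    def dysregulated_pairs(self) -> set[tuple[str, str]]:
        d = self.links[self.links["dysregulated"]]
        return set(zip(d["tf"], d["target"]))

    def reference_grn(self) -> ReferenceGRN:
        df = self.links[["tf", "target"]].copy()
        df["score"] = self.links["beta_normal"].abs()
        df["p_promoter"] = 1e-4
        return ReferenceGRN(df.reset_index(drop=True))

    def to_json(self) -> dict:
        return {
            "tfs": self.tfs, "targets": self.targets,
            "links": self.links.to_dict(orient="list"),
            "intercepts": self.intercepts.to_dict(orient="list"),
            "deg_flags": self.deg_flags, "tf_mean": self.tf_mean,
            "effect_size": self.effect_size, "hazard_coefs": self.hazard_coefs,
            "baseline_hazard": self.baseline_hazard,
            "censor_rate": self.censor_rate,
            "treatment_benefit": self.treatment_benefit,
        }


def generate_grn(n_tf: int, n_target: int, links_per_target: int,
                 frac_dysregulated: float, effect_size: float,
                 rng: np.random.Generator, tf_mean: float = 2.0,
                 ) -> SyntheticTruth:
    """Plant a random network with condition-specific coefficients.

    Base coefficients are drawn +-Uniform(0.3, 0.8).  A ``frac`` of links
    (at most one per target) become dysregulated: beta_tumor moves by
    +-effect_size and the target's tumor intercept shifts by
    effect_size * tf_mean in the same direction, so the target is
    differentially expressed consistently with the intensity change.
    """
    if min(n_tf, n_target, links_per_target) <= 0:
        raise ValueError("counts must be positive")
    if links_per_target > n_tf:
        raise ValueError("links_per_target cannot exceed n_tf")
    if not 0 <= frac_dysregulated <= 1:
        raise ValueError("frac_dysregulated must be in [0, 1]")
    tfs = [f"TF{i:03d}" for i in range(n_tf)]
    targets = [f"G{i:04d}" for i in range(n_target)]
    rows = []
    for tg in targets:
        picks = rng.choice(n_tf, size=links_per_target, replace=False)
        for j in picks:
            beta = rng.uniform(0.3, 0.8) * rng.choice([-1.0, 1.0])
            rows.append((tfs[j], tg, beta, beta, False))
    links = pd.DataFrame(rows, columns=["tf", "target", "beta_normal",
                                        "beta_tumor", "dysregulated"])
    n_dys = int(round(frac_dysregulated * len(links)))
    n_dys = min(n_dys, n_target)
    dys_targets = rng.choice(n_target, size=n_dys, replace=False)
    base = rng.uniform(4.0, 8.0, size=n_target)
    inter = pd.DataFrame({"target": targets, NORMAL: base, TUMOR: base.copy()})
    deg_flags = {tg: False for tg in targets}
    for ti in dys_targets:
        tg = targets[ti]
        link_idx = links.index[links["target"] == tg]
        li = int(rng.choice(link_idx))
        sign = float(rng.choice([-1.0, 1.0]))
        links.loc[li, "beta_tumor"] = links.loc[li, "beta_normal"] + sign * effect_size
        links.loc[li, "dysregulated"] = True
        inter.loc[inter["target"] == tg, TUMOR] += sign * effect_size * tf_mean
        deg_flags[tg] = True
    return SyntheticTruth(tfs=tfs, targets=targets, links=links,
                          intercepts=inter.set_index("target").reset_index(),
                          deg_flags=deg_flags, tf_mean=tf_mean,
                          effect_size=effect_size)


def simulate_expression(truth: SyntheticTruth, n_per_condition: int,
                        noise_sd: float, rng: np.random.Generator,
                        tf_mean: float | None = None,
                        sample_prefix: str = "P") -> ExpressionMatrix:
    """Paired two-condition expression from the planted linear model.

    TF expression is i.i.d. Normal(tf_mean, 1); each target is its
    condition intercept plus the linear TF combination plus Normal(0,
    noise_sd).  Sample ids pair tumor to normal.
    """
    if n_per_condition < 8:
        raise ValueError("need >= 8 samples per condition")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    tf_mean = truth.tf_mean if tf_mean is None else tf_mean
    inter = truth.intercepts.set_index("target")
    cols = {}
    cond = {}
    pairing = {}
    beta_by_cond = {}
    for cnd in (NORMAL, TUMOR):
        bcol = "beta_normal" if cnd == NORMAL else "beta_tumor"
        mat = truth.links.pivot_table(index="target", columns="tf", values=bcol,
                                      aggfunc="first", fill_value=0.0)
        beta_by_cond[cnd] = mat.reindex(index=truth.targets,
                                        columns=truth.tfs, fill_value=0.0)
    for i in range(n_per_condition):
        tf_expr = rng.normal(tf_mean, 1.0, size=len(truth.tfs))
        for cnd, suffix in ((NORMAL, "N"), (TUMOR, "T")):
            sid = f"{sample_prefix}{i:03d}_{suffix}"
            B = beta_by_cond[cnd].to_numpy()
            tg_expr = (inter[cnd].reindex(truth.targets).to_numpy()
                       + B @ tf_expr
                       + rng.normal(0.0, noise_sd, size=len(truth.targets)))
            cols[sid] = np.concatenate([tf_expr, tg_expr])
            cond[sid] = cnd
        pairing[f"{sample_prefix}{i:03d}_T"] = f"{sample_prefix}{i:03d}_N"
    values = pd.DataFrame(cols, index=truth.tfs + truth.targets)
    return ExpressionMatrix(values, pd.Series(cond), pairing)


def simulate_tumor_cohort(truth: SyntheticTruth, n_samples: int, noise_sd: float,
                          rng: np.random.Generator,
                          sample_prefix: str = "S") -> ExpressionMatrix:
    """Tumor-condition-only expression for survival analyses."""
    inter = truth.intercepts.set_index("target")
    B = truth.links.pivot_table(index="target", columns="tf", values="beta_tumor",
                                aggfunc="first", fill_value=0.0)
    B = B.reindex(index=truth.targets, columns=truth.tfs, fill_value=0.0).to_numpy()
    cols = {}
    cond = {}
    for i in range(n_samples):
        tf_expr = rng.normal(truth.tf_mean, 1.0, size=len(truth.tfs))
        tg = (inter[TUMOR].reindex(truth.targets).to_numpy() + B @ tf_expr
              + rng.normal(0.0, noise_sd, size=len(truth.targets)))
        sid = f"{sample_prefix}{i:03d}"
        cols[sid] = np.concatenate([tf_expr, tg])
        cond[sid] = TUMOR
    return ExpressionMatrix(pd.DataFrame(cols, index=truth.tfs + truth.targets),
                            pd.Series(cond))


def _calibrate_censoring(latent: np.ndarray, censor_rate: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Uniform(0, cmax) censoring times with cmax bisected so the expected
    censored fraction matches censor_rate."""
    if censor_rate <= 0:
        return np.full(len(latent), np.inf)

    def frac(cmax: float) -> float:
        return float(np.minimum(latent / cmax, 1.0).mean())

    lo, hi = 1e-6, float(latent.max()) * 2
    while frac(hi) > censor_rate:
        hi *= 2
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    return rng.uniform(0.0, 0.5 * (lo + hi), size=len(latent))


def simulate_survival(expr: ExpressionMatrix, truth: SyntheticTruth,
                      censor_rate: float | None = None,
                      rng: np.random.Generator | None = None,
                      treated_frac: float = 0.0,
                      adjc_types: tuple[str, ...] = ("5FU", "combined"),
                      time_scale: float = 5.0) -> pd.DataFrame:
    """Clinical table for the samples of ``expr`` (tumor cohort).

    Event times are exponential with log-hazard linear in the centered
    expression of the genes in truth.hazard_coefs; treated samples (adjc
    flag) get their hazard multiplied by exp(-treatment_benefit).
    Censoring is independent Uniform(0, cmax) with cmax calibrated to the
    requested rate.  Age/gender/stage are drawn from simple distributions
    and not wired into the hazard.  OS and RFS are independent draws from
    the same model (RFS 20% faster).
    """
    rng = rng or np.random.default_rng(0)
    censor_rate = truth.censor_rate if censor_rate is None else censor_rate
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    samples = list(expr.samples)
    n = len(samples)
    eta = np.zeros(n)
    for g, coef in truth.hazard_coefs.items():
        x = expr.values.loc[g].to_numpy(dtype=float)
        eta += coef * (x - x.mean())
    adjc = (rng.uniform(size=n) < treated_frac).astype(int)
    eta_eff = eta - truth.treatment_benefit * adjc
    rate = truth.baseline_hazard * np.exp(eta_eff)
    latent_os = rng.exponential(1.0 / rate) * time_scale
    latent_rfs = rng.exponential(1.0 / rate) * time_scale * 0.8
    cens = _calibrate_censoring(latent_os, censor_rate, rng)
    os_time = np.minimum(latent_os, cens)
    os_event = (latent_os <= cens).astype(int)
    cens2 = _calibrate_censoring(latent_rfs, censor_rate, rng)
    rfs_time = np.minimum(latent_rfs, cens2)
    rfs_event = (latent_rfs <= cens2).astype(int)
    types = np.where(adjc == 1,
                     rng.choice(list(adjc_types), size=n), "")
    df = pd.DataFrame({
        "sample": samples,
        "os_time": np.round(os_time, 6) + 1e-6,
        "os_event": os_event,
        "rfs_time": np.round(rfs_time, 6) + 1e-6,
        "rfs_event": rfs_event,
        "age": rng.normal(65, 10, size=n).round(1),
        "gender": rng.integers(0, 2, size=n),
        "stage": rng.choice([1, 2, 3, 4], size=n, p=[0.15, 0.35, 0.35, 0.15]),
        "adjc": adjc,
        "adjc_type": types,
    }).set_index("sample")
    return df


PROFILES = {
    "tiny": dict(n_tf=10, n_target=30, links_per_target=2, n_dys=6,
                 n_pairs=16, n_surv=120, treated_frac=0.4),
    "default": dict(n_tf=50, n_target=200, links_per_target=3, n_dys=20,
                    n_pairs=32, n_surv=300, treated_frac=0.0),
    "benefit": dict(n_tf=50, n_target=200, links_per_target=3, n_dys=20,
                    n_pairs=32, n_surv=300, treated_frac=0.45),
}

EFFECT_SIZE = 1.0
NOISE_SD = 0.5
CENSOR_RATE = 0.3
HAZARD_COEF = 0.6
N_HAZARD_LINKS = 4
TREATMENT_BENEFIT = 0.7


@dataclass
class SyntheticDataset:
    expr: ExpressionMatrix
    clinical: pd.DataFrame
    truth: SyntheticTruth


def build_dataset(profile: str, seed: int) -> SyntheticDataset:
    """Generate an in-memory dataset for one profile."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    p = PROFILES[profile]
    rng = np.random.default_rng(seed)
    n_links = p["n_target"] * p["links_per_target"]
    truth = generate_grn(p["n_tf"], p["n_target"], p["links_per_target"],
                         frac_dysregulated=p["n_dys"] / n_links,
                         effect_size=EFFECT_SIZE, rng=rng)
    # hazard genes: TF and target of the first planted dysregulations
    dys = truth.links[truth.links["dysregulated"]].sort_values(["target", "tf"])
    coefs: dict[str, float] = {}
    sgn = 1.0
    for _, row in dys.head(N_HAZARD_LINKS).iterrows():
        for g in (row["tf"], row["target"]):
            if g not in coefs:
                coefs[g] = sgn * HAZARD_COEF
                sgn = -sgn
    truth.hazard_coefs = coefs
    truth.censor_rate = CENSOR_RATE
    truth.treatment_benefit = TREATMENT_BENEFIT if p["treated_frac"] > 0 else 0.0
    paired = simulate_expression(truth, p["n_pairs"], NOISE_SD, rng)
    cohort = simulate_tumor_cohort(truth, p["n_surv"], NOISE_SD, rng)
    values = pd.concat([paired.values, cohort.values], axis=1)
    cond = pd.concat([paired.condition, cohort.condition])
    expr = ExpressionMatrix(values, cond, paired.pairing)
    clinical = simulate_survival(cohort, truth, rng=rng,
                                 treated_frac=p["treated_frac"])
    return SyntheticDataset(expr=expr, clinical=clinical, truth=truth)


def make_fixture(profile: str, seed: int, outdir: str | Path) -> SyntheticDataset:
    """Write a profile's dataset to disk in the pipeline's TSV schemas."""
    ds = build_dataset(profile, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dio.write_expression_tsv(ds.expr.values, outdir / "expr.tsv")
    dio.write_labels_tsv(ds.expr.condition, outdir / "labels.tsv", ds.expr.pairing)
    dio.write_clinical_tsv(ds.clinical.reset_index(), outdir / "clinical.tsv")
    dio.write_edges_tsv(ds.truth.reference_grn(), outdir / "refgrn.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(ds.truth.to_json(), fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return ds
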