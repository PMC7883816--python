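"""Reference regulatory network construction by promoter scanning.

Each promoter (nominally the 1000 bp upstream of the TSS) is scanned on
both strands with every TF's position weight matrix; windows containing N
are skipped.  Site p-values come from the exact discretized score
distribution.  Per TF, family-wise error is controlled at ``fwer_alpha``
by a two-level scheme: Sidak over the m scanned windows of a promoter
(best hit -> promoter-level p) and Bonferroni across promoters.  TFs with
more than ``top_k`` selected targets are trimmed to the ``top_k`` best by
site score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ReferenceGRN
from .motifs import Motif, ScoreDistribution, exact_score_pvalues, log_odds_matrix

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass
class ScanConfig:
    site_p_threshold: float = 1e-4
    fwer_alpha: float = 0.01
    top_k: int = 5000
    pseudocount: float = 0.1
    step: float = 0.01          # score grid, bits

    def __post_init__(self) -> None:
        if not 0 < self.site_p_threshold < 1 or not 0 < self.fwer_alpha < 1:
            raise ValueError("thresholds must be in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class ScanHit:
    tf: str
    gene: str
    offset: int
    strand: str
    score: float
    pvalue: float


def encode_sequences(seqs: list[str]) -> np.ndarray:
    """Equal-length sequences -> int8 matrix (A=0..T=3, N and others=4)."""
    lens = {len(s) for s in seqs}
    if len(lens) != 1:
        raise ValueError("encode_sequences requires equal-length sequences")
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE[buf].reshape(len(seqs), lens.pop())


def estimate_background(seqs: dict[str, str]) -> np.ndarray:
    """0-order base frequencies over a promoter set (N excluded)."""
    counts = np.zeros(4)
    for s in seqs.values():
        enc = _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
        counts += np.bincount(enc[enc < 4], minlength=4)[:4]
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


class MotifScanner:
    """A PWM compiled for scanning: log-odds matrices for both strands and
    the exact score-to-p-value table, shared across promoters."""

    def __init__(self, motif: Motif, background: np.ndarray | None = None,
                 cfg: ScanConfig | None = None):
        self.cfg = cfg or ScanConfig()
        self.motif = motif
        self.background = np.asarray(
            background if background is not None else motif.background, dtype=float)
        self.background = self.background / self.background.sum()
        self.S = log_odds_matrix(motif, self.background, self.cfg.pseudocount)
        self.dist: ScoreDistribution = exact_score_pvalues(
            self.S, self.background, self.cfg.step)
        self.I = self.dist.int_matrix
        # reverse-complement scoring matrix: position and base both flipped
        self.I_rc = self.I[::-1, ::-1].copy()
        self.S_rc = self.S[::-1, ::-1].copy()

    @property
    def width(self) -> int:
        return self.motif.width

    def _window_scores(self, enc: np.ndarray, imat: np.ndarray) -> np.ndarray:
        """Integer scores of all windows for many sequences at once.

        enc: (n_seqs, L) int codes; windows with any N get INT_MIN.
        """
        w = self.width
        n, L = enc.shape
        n_win = L - w + 1
        if n_win <= 0:
            return np.zeros((n, 0), dtype=np.int64)
        safe = np.minimum(enc, 3)
        total = np.zeros((n, n_win), dtype=np.int64)
        for j in range(w):
            total += imat[j][safe[:, j:j + n_win]]
        valid = self.valid_windows(enc)
        total[~valid] = np.iinfo(np.int64).min
        return total

    def valid_windows(self, enc: np.ndarray) -> np.ndarray:
        """Boolean (n_seqs, n_win): window free of N on either strand."""
        w = self.width
        n, L = enc.shape
        n_win = L - w + 1
        bad = (enc >= 4).astype(np.int32)
        cum = np.concatenate([np.zeros((n, 1), dtype=np.int32), np.cumsum(bad, axis=1)], axis=1)
        return (cum[:, w:] - cum[:, :-w]) == 0

    def scan(self, seq: str, gene: str = "") -> list[ScanHit]:
        """All hits with site p < threshold on both strands, sorted by p."""
        w = self.width
        if len(seq) < w:
            warnings.warn(f"sequence shorter than motif width {w}; no windows")
            return []
        enc = encode_sequences([seq])
        fwd = self._window_scores(enc, self.I)[0]
        rev = self._window_scores(enc, self.I_rc)[0]
        hits: list[ScanHit] = []
        for strand, ints in (("+", fwd), ("-", rev)):
            ok = ints > np.iinfo(np.int64).min
            pvals = self.dist.pvalue_int(ints[ok])
            offsets = np.where(ok)[0]
            for off, iv, p in zip(offsets, ints[ok], pvals):
                if p < self.cfg.site_p_threshold:
                    hits.append(ScanHit(self.motif.tf_name, gene, int(off), strand,
                                        float(iv * self.cfg.step), float(p)))
        hits.sort(key=lambda h: (h.pvalue, h.offset, h.strand))
        return hits

    def best_site_stats(self, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per sequence: best integer score over both strands, its p-value,
        and the Sidak window count m (both strands, N windows excluded)."""
        fwd = self._window_scores(enc, self.I)
        rev = self._window_scores(enc, self.I_rc)
        best = np.maximum(fwd.max(axis=1, initial=np.iinfo(np.int64).min),
                          rev.max(axis=1, initial=np.iinfo(np.int64).min))
        m = 2 * self.valid_windows(enc).sum(axis=1)
        p = np.where(m > 0, self.dist.pvalue_int(best), 1.0)
        return best, p, m


def scan_sequence(seq: str, motif: Motif, cfg: ScanConfig | None = None,
                  background: np.ndarray | None = None, gene: str = "") -> list[ScanHit]:
    """Convenience wrapper: compile the motif and scan one sequence."""
    return MotifScanner(motif, background, cfg).scan(seq, gene)


def sidak_promoter_pvalue(best_site_p: np.ndarray, n_windows: np.ndarray) -> np.ndarray:
    """Promoter-level p for the best of m windows: 1 - (1 - p)^m."""
    p = np.asarray(best_site_p, dtype=float)
    m = np.asarray(n_windows, dtype=float)
    out = -np.expm1(m * np.log1p(-np.minimum(p, 1.0 - 1e-300)))
    return np.where(m > 0, np.minimum(out, 1.0), 1.0)


def fwer_select_targets(promoter_best: pd.DataFrame, n_promoters: int,
                        cfg: ScanConfig | None = None) -> pd.DataFrame:
    """Select targets per TF with family-wise error < fwer_alpha.

    ``promoter_best`` columns: tf, target, best_site_p, n_windows and
    optionally score.  The promoter-level p (Sidak over windows) is
    compared against fwer_alpha / n_promoters (Bonferroni across
    promoters); under the null the probability of any false target per TF
    is below fwer_alpha.
    """
    cfg = cfg or ScanConfig()
    if n_promoters <= 0:
        raise ValueError("n_promoters must be positive")
    df = promoter_best.copy()
    df["p_promoter"] = sidak_promoter_pvalue(df["best_site_p"].to_numpy(),
                                             df["n_windows"].to_numpy())
    selected = df[df["p_promoter"] < cfg.fwer_alpha / n_promoters].copy()
    return selected.reset_index(drop=True)


def trim_top_targets(edges: pd.DataFrame, top_k: int) -> ReferenceGRN:
    """Keep at most top_k targets per TF, ranked by best site score
    descending; ties broken by promoter p ascending then target id."""
    df = edges.copy()
    if "p_promoter" not in df.columns:
        df["p_promoter"] = 1.0
    df = df.sort_values(["tf", "score", "p_promoter", "target"],
                        ascending=[True, False, True, True], kind="stable")
    df = df.groupby("tf", sort=True).head(top_k)
    return ReferenceGRN(df[["tf", "target", "score", "p_promoter"]].reset_index(drop=True))


def build_reference_grn(promoters: dict[str, str], motifs: list[Motif],
                        cfg: ScanConfig | None = None,
                        background: np.ndarray | None = None) -> tuple[ReferenceGRN, dict]:
    """Full reference-network construction from promoters and motifs."""
    cfg = cfg or ScanConfig()
    if background is None:
        background = estimate_background(promoters)
    genes = sorted(promoters)
    rows = []
    by_len: dict[int, list[str]] = {}
    for g in genes:
        by_len.setdefault(len(promoters[g]), []).append(g)
    for motif in motifs:
        scanner = MotifScanner(motif, background, cfg)
        for L, gs in sorted(by_len.items()):
            if L < scanner.width:
                continue
            enc = encode_sequences([promoters[g] for g in gs])
            best, p, m = scanner.best_site_stats(enc)
            keep = p < cfg.site_p_threshold
            for gi in np.where(keep)[0]:
                rows.append((motif.tf_name, gs[gi], float(best[gi] * cfg.step),
                             float(p[gi]), int(m[gi])))
    cand = pd.DataFrame(rows, columns=["tf", "target", "score", "best_site_p", "n_windows"])
    if cand.empty:
        return ReferenceGRN(), {"n_tfs": 0, "n_edges": 0}
    selected = fwer_select_targets(cand, n_promoters=len(genes), cfg=cfg)
    grn = trim_top_targets(selected, cfg.top_k)
    stats = {"n_tfs": len(grn.tfs), "n_edges": len(grn),
             "n_candidate_hits": int(len(cand)), "n_promoters": len(genes)}
    return grn, stats
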