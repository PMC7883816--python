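"""Position-weight-matrix machinery: MEME parsing, log-odds scoring, and
exact site p-values by dynamic programming over a discretized score grid.

The site p-value of a log-odds score s is P(score of a random w-mer >= s)
under a 0-order background model.  Scores are discretized to an integer
grid (default 1/100 bit) and the exact tail distribution is obtained by
convolving the per-position score distributions (Staden's method); the
window score is floored onto the same grid, so the reported p-value is
conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
UNIFORM = np.full(4, 0.25)


@dataclass
class Motif:
    """A TF binding motif: per-position base probabilities plus background."""

    tf_name: str
    pfm: np.ndarray                     # w x 4 probabilities over A,C,G,T
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pfm.ndim != 2 or self.pfm.shape[1] != 4:
            raise ValueError("pfm must be w x 4")
        if self.width < 3:
            raise ValueError("motif width must be >= 3")
        sums = self.pfm.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 0.05):
            raise ValueError(f"motif {self.tf_name}: pfm rows must sum to 1")
        self.pfm = self.pfm / sums[:, None]

    @property
    def width(self) -> int:
        return self.pfm.shape[0]


def read_meme(path: str) -> list[Motif]:
    """Parse a MEME text (minimal) motif file.

    One Motif per MOTIF block; the file-level background line is used if
    present, otherwise uniform.  Malformed probability rows raise with the
    offending line number.
    """
    with open(path) as fh:
        lines = fh.readlines()
    background = UNIFORM.copy()
    motifs: list[Motif] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            i += 1
            tokens: list[str] = []
            while i < n and lines[i].strip() and not lines[i].startswith("MOTIF"):
                tokens.extend(lines[i].split())
                i += 1
            freq = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens) - 1, 2)}
            background = np.array([freq.get(b, 0.25) for b in ALPHABET])
            background = background / background.sum()
            continue
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"line {i + 1}: MOTIF line without a name")
            name = parts[1]
            i += 1
            # seek the letter-probability header
            while i < n and "letter-probability" not in lines[i]:
                if lines[i].startswith("MOTIF"):
                    raise ValueError(f"line {i + 1}: MOTIF {name} has no matrix")
                i += 1
            if i >= n:
                raise ValueError(f"MOTIF {name}: missing letter-probability matrix")
            header = lines[i]
            width = None
            for tok, nxt in zip(header.split(), header.split()[1:] + [""]):
                if tok == "w=":
                    width = int(nxt)
            i += 1
            rows = []
            while i < n:
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                vals = stripped.split()
                if len(vals) != 4:
                    raise ValueError(f"line {i + 1}: expected 4 columns, got {len(vals)}")
                row = [float(v) for v in vals]
                if abs(sum(row) - 1.0) > 0.05:
                    raise ValueError(f"line {i + 1}: probability row sums to {sum(row):.3f}")
                rows.append(row)
                i += 1
            if width is not None and len(rows) != width:
                raise ValueError(f"MOTIF {name}: w= {width} but {len(rows)} rows")
            motifs.append(Motif(name, np.array(rows), background))
            continue
        i += 1
    return motifs


def log_odds_matrix(motif: Motif, background: np.ndarray | None = None,
                    pseudocount: float = 0.1) -> np.ndarray:
    """w x 4 log2-odds scores with pseudocount regularization.

    score[i, b] = log2((pfm[i, b] + pc * bg[b]) / ((1 + pc) * bg[b])).
    """
    bg = np.asarray(background if background is not None else motif.background, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background probabilities must be positive")
    bg = bg / bg.sum()
    num = motif.pfm + pseudocount * bg[None, :]
    return np.log2(num / ((1.0 + pseudocount) * bg[None, :]))


@dataclass
class ScoreDistribution:
    """Exact tail distribution of the discretized log-odds score.

    ``int_matrix`` holds floor(score / step); ``tail[k]`` is the exact
    probability, under i.i.d. background, that a random w-mer's integer
    score is >= min_score + k.
    """

    int_matrix: np.ndarray
    step: float
    min_score: int
    tail: np.ndarray

    def pvalue_int(self, int_scores) -> np.ndarray:
        """Tail probability of integer score(s); scores below the minimum
        achievable get p = 1, above the maximum get the smallest tail."""
        idx = np.asarray(int_scores) - self.min_score
        idx = np.clip(idx, 0, len(self.tail) - 1)
        out = self.tail[idx]
        below = np.asarray(int_scores) < self.min_score
        return np.where(below, 1.0, out)

    def pvalue(self, scores) -> np.ndarray:
        return self.pvalue_int(np.floor(np.asarray(scores) / self.step).astype(np.int64))


def exact_score_pvalues(score_matrix: np.ndarray, background: np.ndarray,
                        step: float = 0.01) -> ScoreDistribution:
    """Exact p-values for every achievable discretized total score.

    Dynamic programming: the pmf of the partial score is convolved with
    each position's 4-point score distribution, weighted by the background.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    imat = np.floor(np.asarray(score_matrix, dtype=float) / step).astype(np.int64)
    w = imat.shape[0]
    lo = int(imat.min(axis=1).sum())
    hi = int(imat.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # offset bookkeeping: pmf[k] = P(partial score == partial_lo + k)
    pmf[0] = 1.0
    partial_lo = 0
    size = 1
    for i in range(w):
        row = imat[i]
        rlo = int(row.min())
        new_size = size + int(row.max()) - rlo
        new = np.zeros(new_size)
        for b in range(4):
            off = int(row[b]) - rlo
            new[off:off + size] += bg[b] * pmf[:size]
        pmf[:new_size] = new
        size = new_size
        partial_lo += rlo
    assert partial_lo == lo
    tail = np.cumsum(pmf[:size][::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    return ScoreDistribution(int_matrix=imat, step=step, min_score=lo, tail=tail)
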