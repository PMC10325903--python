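"""Position weight matrices, information content, and sequence scanning.

A PWM is an L x 4 matrix of base probabilities in A,C,G,T order.  Per-column
information content is ``IC = 2 + sum_b p_b log2 p_b`` bits (0 for a uniform
column, 2 for a fixed base).  Scanning uses natural-log odds against a uniform
0.25 background — the same scale Homer writes into its ``.motif`` headers, so
imported thresholds work unchanged.  Positions containing N never match: their
log-odds contribution is effectively minus infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import BASES, encode_seqs, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_NEG_INF = -1e9  # effective -inf that stays finite in sums


def column_information_content(p) -> float:
    """Information content of one PWM column, in bits."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative probability in PWM column")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"column probabilities sum to {p.sum():.6g}, not 1")
    nz = p[p > 0]
    ic = 2.0 + float(np.sum(nz * np.log2(nz)))
    return min(2.0, max(0.0, ic))


@dataclass
class PWM:
    """Base-probability matrix with optional log-odds match threshold.

    `score_threshold` is in natural-log-odds units against a uniform
    background; a window matches when its score is >= the threshold.
    """

    probs: np.ndarray
    name: str = ""
    score_threshold: float | None = None

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("PWM probabilities must be an L x 4 matrix")
        if np.any(p < 0):
            raise ValueError("PWM probabilities must be non-negative")
        sums = p.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("PWM column with zero total probability")
        self.probs = p / sums[:, None]

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def information_content(self) -> np.ndarray:
        """Per-column IC in bits."""
        return np.array([column_information_content(row) for row in self.probs])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    def log_odds(self) -> np.ndarray:
        """(L, 5) natural-log odds vs uniform background; column 4 (N) never matches."""
        lo = np.full((self.length, 5), _NEG_INF)
        with np.errstate(divide="ignore"):
            lo[:, :4] = np.where(
                self.probs > 0, np.log(np.maximum(self.probs, 1e-300) / 0.25), _NEG_INF
            )
        return lo

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.probs[::-1, ::-1].copy(),
            name=self.name + "_rc" if self.name else "",
            score_threshold=self.score_threshold,
        )


@dataclass
class CoreSite:
    """A 4-bp core site extracted from a longer motif."""

    pwm4: PWM
    offset: int
    consensus: str
    mean_ic: float

    def __post_init__(self):
        if self.pwm4.length != 4:
            raise ValueError("core site PWM must have length 4")


def consensus_to_pwm(consensus: str, mismatches: int = 0, eps: float = 1e-3,
                     name: str | None = None) -> PWM:
    """Build a PWM whose match set is the Hamming ball around an IUPAC consensus.

    Consensus bases get probability (1 - (4-k)*eps)/k for a degenerate code of
    k allowed bases; off-consensus bases get eps.  The score threshold is set
    midway between the worst sequence at <= `mismatches` mismatches and the
    best sequence at `mismatches`+1, so thresholded scanning reproduces
    Hamming-ball matching exactly (the seq2profile construction).
    """
    consensus = consensus.upper()
    rows = []
    allowed_scores = []
    mismatch_drops = []  # score lost by mismatching each column (where possible)
    for b in consensus:
        if b not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {b!r} in consensus")
        allowed = IUPAC[b]
        k = len(allowed)
        p_allow = (1.0 - (4 - k) * eps) / k
        row = [p_allow if base in allowed else eps for base in BASES]
        rows.append(row)
        a_score = np.log(p_allow / 0.25)
        allowed_scores.append(a_score)
        if k < 4:
            d_score = np.log(eps / 0.25) if eps > 0 else -np.inf
            mismatch_drops.append(a_score - d_score)
    max_score = float(np.sum(allowed_scores))
    drops = np.sort(np.asarray(mismatch_drops))[::-1]
    m = mismatches
    if m >= len(drops):
        worst_allowed = max_score - float(drops.sum())
        threshold = worst_allowed - 0.5  # every sequence matches
    else:
        worst_allowed = max_score - float(drops[:m].sum()) if m else max_score
        best_disallowed = max_score - float(np.sort(drops)[: m + 1].sum())
        if worst_allowed <= best_disallowed:
            raise ValueError("eps too large to separate the Hamming ball by score")
        threshold = 0.5 * (worst_allowed + best_disallowed)
    return PWM(np.asarray(rows), name=name or f"{consensus}_mm{mismatches}",
               score_threshold=threshold)


def _forward_scores(lo: np.ndarray, codes: np.ndarray) -> np.ndarray:
    motif_len = lo.shape[0]
    n_pos = len(codes) - motif_len + 1
    if n_pos <= 0:
        return np.empty(0)
    scores = np.zeros(n_pos)
    for j in range(motif_len):
        scores += lo[j, codes[j : j + n_pos]]
    return scores


def scan_sequence(pwm: PWM, seq: str, both_strands: bool = True):
    """All motif matches in a sequence.

    Returns a position-sorted list of ``(position, strand, score)`` where
    position is the forward-strand coordinate of the match's leftmost base and
    strand is '+' or '-'.  Sequences shorter than the motif yield no hits.
    """
    threshold = pwm.score_threshold if pwm.score_threshold is not None else -np.inf
    codes = encode_seqs([seq])[0] if seq else np.empty(0, dtype=np.uint8)
    lo = pwm.log_odds()
    hits = []
    scores = _forward_scores(lo, codes)
    for pos in np.nonzero(scores >= threshold)[0]:
        hits.append((int(pos), "+", float(scores[pos])))
    if both_strands:
        rc_codes = encode_seqs([reverse_complement(seq)])[0] if seq else codes
        rscores = _forward_scores(lo, rc_codes)
        for pos in np.nonzero(rscores >= threshold)[0]:
            fwd_pos = len(seq) - int(pos) - pwm.length
            hits.append((fwd_pos, "-", float(rscores[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def pool_has_match(pwm: PWM, arr: np.ndarray, both_strands: bool = True) -> np.ndarray:
    """Vectorized per-read 'contains >=1 motif match' over an encoded pool."""
    threshold = pwm.score_threshold if pwm.score_threshold is not None else -np.inf
    n, length = arr.shape
    motif_len = pwm.length
    if length < motif_len:
        return np.zeros(n, dtype=bool)
    n_pos = length - motif_len + 1
    los = [pwm.log_odds()]
    if both_strands:
        los.append(pwm.reverse_complement().log_odds())
    hit = np.zeros(n, dtype=bool)
    for lo in los:
        scores = np.zeros((n, n_pos))
        for j in range(motif_len):
            scores += lo[j, arr[:, j : j + n_pos].astype(np.intp)]
        hit |= (scores >= threshold).any(axis=1)
    return hit


def mean_window_ic(pwm: PWM, start: int, width: int) -> float:
    """Arithmetic mean of per-column IC over a window of the motif, in bits."""
    if width <= 0:
        raise ValueError("window width must be positive")
    if start < 0 or start + width > pwm.length:
        raise ValueError("window outside motif")
    return float(np.mean(pwm.information_content()[start : start + width]))
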