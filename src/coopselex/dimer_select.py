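"""Screening long motifs (16-18 bp) for homodimer sites.

A candidate dimer site is two non-overlapping 4-bp core windows at least 2 bp
apart whose summed mean information content is maximal within the long motif.
A motif passes the screen when (1) both cores have mean IC above a floor,
(2) the core IC stands out against the surrounding columns by a minimum
ratio (rejecting flat, over-amplification-driven profiles), and (3) the long
motif is present in a minimum fraction of the final-cycle pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from ._seq import (
    RC_WORD,
    WORD_SENTINEL,
    encode_seqs,
    int_to_kmer,
    word_matrix,
)
from .motif_core import PWM, CoreSite, mean_window_ic, pool_has_match


@dataclass
class DimerModel:
    """Two 4-bp core sites + spacer extracted from a long motif."""

    site1: CoreSite
    site2: CoreSite
    spacer: int
    orientation: str = "FF"
    source_motif: PWM | None = None
    abundance_cycle4: float | None = None

    def __post_init__(self):
        if self.spacer < 0:
            raise ValueError("spacer must be >= 0")
        if self.orientation not in ("FF", "FR", "RF"):
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if self.site1.offset + 4 + self.spacer != self.site2.offset:
            raise ValueError("site offsets inconsistent with spacer")
        if self.abundance_cycle4 is not None and not 0 <= self.abundance_cycle4 <= 1:
            raise ValueError("abundance must be a fraction in [0, 1]")


@dataclass
class DimerScreenResult:
    candidate: DimerModel | None
    ic_pass: bool
    flank_ratio_pass: bool
    abundance_pass: bool
    reasons: list[str] = field(default_factory=list)
    site_ics: tuple[float, float] | None = None
    surround_ic: float | None = None
    abundance: float | None = None


def _core_site(pwm: PWM, offset: int) -> CoreSite:
    sub = PWM(pwm.probs[offset : offset + 4].copy())
    return CoreSite(
        pwm4=sub,
        offset=offset,
        consensus=sub.consensus,
        mean_ic=mean_window_ic(pwm, offset, 4),
    )


def extract_core_sites(long_motif: PWM, min_spacer: int = 2) -> tuple[CoreSite, CoreSite]:
    """The pair of non-overlapping 4-bp windows maximizing summed mean IC.

    Windows must be separated by at least `min_spacer` bp.  Ties break toward
    the leftmost first window, then the smallest spacer.
    """
    length = long_motif.length
    if length < 8 + min_spacer:
        raise ValueError(
            f"motif length {length} too short for two 4-mers {min_spacer} bp apart"
        )
    ic = long_motif.information_content()
    win = np.convolve(ic, np.ones(4) / 4.0, mode="valid")  # mean IC per window
    best = None
    for i in range(length - 8 - min_spacer + 1):
        for j in range(i + 4 + min_spacer, length - 3):
            key = (-(win[i] + win[j]), i, j - i - 4)
            if best is None or key < best[0]:
                best = (key, i, j)
    _, i, j = best
    return _core_site(long_motif, i), _core_site(long_motif, j)


def screen_dimer(
    long_motif: PWM,
    cycle4_reads,
    ic_min: float = 0.6,
    flank_ratio_min: float = 1.5,
    abundance_min: float = 0.05,
    surround: str = "pooled",
    min_spacer: int = 2,
) -> DimerScreenResult:
    """Apply the three dimer-site criteria to one long motif.

    `surround` selects which columns the core IC is compared against:
    ``pooled`` (flanks and spacer together, the default), ``flanks_only``
    or ``spacer_only``.
    """
    if not len(cycle4_reads):
        raise ValueError("cycle-4 pool is empty")
    site1, site2 = extract_core_sites(long_motif, min_spacer=min_spacer)
    ic = long_motif.information_content()
    core_cols = set(range(site1.offset, site1.offset + 4)) | set(
        range(site2.offset, site2.offset + 4)
    )
    spacer_cols = set(range(site1.offset + 4, site2.offset))
    if surround == "pooled":
        sur_cols = [j for j in range(long_motif.length) if j not in core_cols]
    elif surround == "flanks_only":
        sur_cols = [
            j for j in range(long_motif.length)
            if j not in core_cols and j not in spacer_cols
        ]
    elif surround == "spacer_only":
        sur_cols = sorted(spacer_cols)
    else:
        raise ValueError(f"unknown surround mode {surround!r}")
    surround_ic = float(np.mean(ic[sur_cols])) if sur_cols else 0.0

    ic_pass = site1.mean_ic > ic_min and site2.mean_ic > ic_min
    flank_ratio_pass = (
        site1.mean_ic >= flank_ratio_min * surround_ic
        and site2.mean_ic >= flank_ratio_min * surround_ic
        and (site1.mean_ic > 0 or surround_ic == 0)
    )
    # constant positive IC profile => ratio 1 < flank_ratio_min => fail
    if surround_ic > 0 and (
        site1.mean_ic < flank_ratio_min * surround_ic
        or site2.mean_ic < flank_ratio_min * surround_ic
    ):
        flank_ratio_pass = False

    # Criterion 3: fraction of final-cycle reads carrying the motif.  With an
    # imported (Homer) threshold the full PWM is scanned; motifs from internal
    # discovery carry no calibrated threshold, so the dimer configuration
    # itself (both cores at the motif's spacer, either strand) is counted.
    spacer = site2.offset - site1.offset - 4
    arr = encode_seqs(cycle4_reads)
    if long_motif.score_threshold is not None:
        abundance = float(np.mean(pool_has_match(long_motif, arr, both_strands=True)))
    else:
        from .enrichment import config_position_matrix

        hits = config_position_matrix(
            word_matrix(arr), site1.consensus, site2.consensus, spacer, "FF", 0
        )
        abundance = float(hits.any(axis=1).mean()) if hits.size else 0.0
    abundance_pass = abundance >= abundance_min

    reasons = []
    if not ic_pass:
        reasons.append("core_ic_below_min")
    if not flank_ratio_pass:
        reasons.append("flank_ratio_below_min")
    if not abundance_pass:
        reasons.append("abundance_below_min")
    candidate = None
    if ic_pass and flank_ratio_pass and abundance_pass:
        candidate = DimerModel(
            site1=site1,
            site2=site2,
            spacer=spacer,
            orientation="FF",
            source_motif=long_motif,
            abundance_cycle4=abundance,
        )
    return DimerScreenResult(
        candidate=candidate,
        ic_pass=ic_pass,
        flank_ratio_pass=flank_ratio_pass,
        abundance_pass=abundance_pass,
        reasons=reasons,
        site_ics=(site1.mean_ic, site2.mean_ic),
        surround_ic=surround_ic,
        abundance=abundance,
    )


def _seed_keys(arr: np.ndarray, min_spacer: int, max_spacer: int) -> np.ndarray:
    """Canonical (word1, spacer, word2) seed keys present per read (deduplicated)."""
    w = word_matrix(arr)
    n, n_pos = w.shape
    chunks = []
    for s in range(min_spacer, max_spacer + 1):
        gap = 4 + s
        if n_pos <= gap:
            continue
        w1 = w[:, : n_pos - gap]
        w2 = w[:, gap:]
        valid = (w1 != WORD_SENTINEL) & (w2 != WORD_SENTINEL)
        ridx, cidx = np.nonzero(valid)
        a = w1[ridx, cidx].astype(np.int64)
        b = w2[ridx, cidx].astype(np.int64)
        # canonicalize with the reverse complement of the whole configuration
        ra = RC_WORD[b].astype(np.int64)
        rb = RC_WORD[a].astype(np.int64)
        key_f = (a << 12) | (s << 8) | b
        key_r = (ra << 12) | (s << 8) | rb
        key = np.minimum(key_f, key_r)
        chunks.append((ridx.astype(np.int64) << 21) | key)
    if not chunks:
        return np.empty(0, dtype=np.int64)
    allk = np.unique(np.concatenate(chunks))  # dedupe per (read, seed)
    return allk & ((1 << 21) - 1)


def _seed_frequencies(arr: np.ndarray, min_spacer: int, max_spacer: int) -> dict[int, int]:
    keys = _seed_keys(arr, min_spacer, max_spacer)
    uniq, counts = np.unique(keys, return_counts=True)
    return dict(zip(uniq.tolist(), counts.tolist()))


def _build_seed_pwm(arr: np.ndarray, w1: int, s: int, w2: int, length: int) -> PWM | None:
    """Align reads on the gapped seed and build a PWM of the requested length."""
    span = 8 + s
    flank_left = (length - span) // 2
    w = word_matrix(arr)
    n, n_pos = w.shape
    gap = 4 + s
    if n_pos <= gap:
        return None
    counts = np.full((length, 4), 0.5)  # pseudocount
    rw1, rw2 = int(RC_WORD[w2]), int(RC_WORD[w1])
    for words, revcomp_read in (((w1, w2), False), ((rw1, rw2), True)):
        a, b = words
        hit = (w[:, : n_pos - gap] == a) & (w[:, gap:] == b)
        ridx, cidx = np.nonzero(hit)
        if not len(ridx):
            continue
        # first occurrence per read
        first = {}
        for r, c in zip(ridx, cidx):
            if r not in first:
                first[r] = c
        for r, c in first.items():
            row = arr[r].astype(np.int16)
            if revcomp_read:
                row = 3 - row[::-1]  # complement of 0..3; N(4) -> -1, masked below
            start = c if not revcomp_read else len(row) - c - span
            lo = start - flank_left
            for j in range(length):
                p = lo + j
                if 0 <= p < len(row) and 0 <= row[p] <= 3:
                    counts[j, row[p]] += 1
    if counts.sum() <= length * 2.0 + 1e-9:  # nothing aligned beyond pseudocounts
        return None
    return PWM(counts, name=f"{int_to_kmer(w1)}_{s}_{int_to_kmer(w2)}")


def discover_long_motifs(
    cycle4_reads,
    cycle0_reads,
    lengths=(16, 18),
    top_k: int = 3,
    min_spacer: int = 2,
    max_spacer: int = 12,
    min_seed_frac: float = 1e-3,
) -> list[PWM]:
    """Greedy seeded long-motif discovery (a lightweight Homer stand-in).

    Gapped 4mer-pair seeds (4mer, spacer, 4mer) are ranked by their cycle-4 /
    cycle-0 read-frequency ratio; for each top seed, cycle-4 reads containing
    it are aligned on the seed span and stacked into a PWM.  Returns PWMs in
    decreasing seed-enrichment order; empty when no seed reaches
    `min_seed_frac` of cycle-4 reads.
    """
    if not len(cycle4_reads) or not len(cycle0_reads):
        raise ValueError("both cycle-4 and cycle-0 pools are required")
    arr4 = encode_seqs(cycle4_reads)
    arr0 = encode_seqs(cycle0_reads)
    n4, n0 = len(cycle4_reads), len(cycle0_reads)
    freq4 = _seed_frequencies(arr4, min_spacer, max_spacer)
    freq0 = _seed_frequencies(arr0, min_spacer, max_spacer)
    # per-position forward word frequencies, for a co-occurrence null:
    # a seed must be enriched beyond what its two 4mers predict independently
    # (a strongly selected monomer creates chance pairings at every spacer)
    w4 = word_matrix(arr4)
    valid = w4[w4 != WORD_SENTINEL]
    word_p = np.bincount(valid, minlength=257) / max(1, valid.size)
    n_pos_total = w4.shape[1]
    scored = []
    for key, c4 in freq4.items():
        if c4 / n4 < min_seed_frac:
            continue
        a = int(key >> 12)
        s = int((key >> 8) & 0xF)
        b = int(key & 0xFF)
        n_pos = max(1, n_pos_total - 4 - s)
        expected = n4 * n_pos * (
            word_p[a] * word_p[b] + word_p[RC_WORD[b]] * word_p[RC_WORD[a]]
        )
        # fold + Poisson tail: hundreds of thousands of candidate seeds make
        # mild fold excesses at small counts routine chance events
        if c4 < 3.0 * expected or poisson.sf(c4 - 1, max(expected, 1e-3)) > 1e-9:
            continue
        c0 = freq0.get(key, 0)
        ratio = (c4 / n4) / ((c0 + 0.5) / n0)
        scored.append((ratio, c4, key))
    scored.sort(reverse=True)
    # require genuine enrichment over the unselected library
    scored = [t for t in scored if t[0] > 2.0]
    pwms = []
    for ratio, _, key in scored[:top_k]:
        w1 = int(key >> 12)
        s = int((key >> 8) & 0xF)
        w2 = int(key & 0xFF)
        usable = [L for L in sorted(lengths) if L >= 8 + s]
        if not usable:
            continue
        pwm = _build_seed_pwm(arr4, w1, s, w2, usable[0])
        if pwm is not None:
            pwms.append(pwm)
    return pwms
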