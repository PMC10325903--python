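"""Low-level DNA encoding helpers shared by the counting and simulation code.

Sequences are encoded as uint8 arrays with A,C,G,T -> 0..3 and anything else
(N, padding) -> 4.  4-mers are packed into integers 0..255; windows touching a
non-ACGT base get the sentinel 256 so lookup tables of length 257 can treat
them as never-matching.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

BASES = "ACGT"
N_CODE = 4
WORD_SENTINEL = 256

_CODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seqs(seqs, pad_to: int | None = None) -> np.ndarray:
    """Encode sequences into an (n, L) uint8 matrix, padding short ones with 4."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    length = max(len(s) for s in seqs)
    if pad_to is not None:
        length = max(length, pad_to)
    out = np.full((len(seqs), length), N_CODE, dtype=np.uint8)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    return out


def decode_seqs(arr: np.ndarray) -> list[str]:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return ["".join(chr(c) for c in lut[row]).rstrip("N") for row in arr]


def word_matrix(arr: np.ndarray) -> np.ndarray:
    """Pack every 4-bp window into an int; windows with N -> 256 sentinel."""
    n, length = arr.shape
    if length < 4:
        return np.full((n, 0), WORD_SENTINEL, dtype=np.int32)
    a = arr.astype(np.int32)
    w = (a[:, :-3] << 6) + (a[:, 1:-2] << 4) + (a[:, 2:-1] << 2) + a[:, 3:]
    invalid = (
        (arr[:, :-3] == N_CODE)
        | (arr[:, 1:-2] == N_CODE)
        | (arr[:, 2:-1] == N_CODE)
        | (arr[:, 3:] == N_CODE)
    )
    w[invalid] = WORD_SENTINEL
    return w


def kmer_to_int(kmer: str) -> int:
    v = 0
    for b in kmer:
        v = (v << 2) | BASES.index(b)
    return v


def int_to_kmer(v: int, k: int = 4) -> str:
    return "".join(BASES[(v >> (2 * (k - 1 - i))) & 3] for i in range(k))


def _build_rc_word_table() -> np.ndarray:
    tab = np.empty(257, dtype=np.int32)
    for v in range(256):
        tab[v] = kmer_to_int(reverse_complement(int_to_kmer(v)))
    tab[WORD_SENTINEL] = WORD_SENTINEL
    return tab


RC_WORD = _build_rc_word_table()


def hamming_ball_words(consensus: str, mismatches: int = 0) -> list[int]:
    """All 4-mers within `mismatches` of an IUPAC 4-mer consensus."""
    from .motif_core import IUPAC  # local import to avoid a cycle

    allowed = [IUPAC[b] for b in consensus.upper()]
    words = set()
    positions = range(4)
    for flip in range(mismatches + 1):
        for idx in combinations(positions, flip):
            choice_sets = [
                BASES if j in idx else allowed[j] for j in positions
            ]
            for bases in product(*choice_sets):
                dist = sum(b not in allowed[j] for j, b in enumerate(bases))
                if dist <= mismatches:
                    words.add(kmer_to_int("".join(bases)))
    return sorted(words)


def site_lut(consensus: str, mismatches: int = 0, both_strands: bool = False) -> np.ndarray:
    """Boolean table over packed words: does the word match the site?"""
    lut = np.zeros(257, dtype=bool)
    lut[hamming_ball_words(consensus, mismatches)] = True
    if both_strands:
        lut = lut | lut[RC_WORD]
    lut[WORD_SENTINEL] = False
    return lut


def rc_lut(lut: np.ndarray) -> np.ndarray:
    """Table matching the reverse complements of the words another table matches."""
    out = lut[RC_WORD]
    out[WORD_SENTINEL] = False
    return out
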