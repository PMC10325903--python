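"""Dimer vs monomer site enrichment across SELEX cycles and the EF statistic.

The fraction of reads carrying the exact dimer configuration (two core sites
at the model's spacer and orientation, either strand) and the fraction of
dimer-free reads carrying at least one core-site match are tracked per cycle.
Fold changes against the initial library are linearized with a natural log,
slopes are fitted by ordinary least squares, and the enrichment factor is

    EF = slope_dimer / mean(slope_site1, slope_site2).

EF > 2 is the positivity gate for a cooperative prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._seq import encode_seqs, rc_lut, site_lut, word_matrix
from .dimer_select import DimerModel
from .motif_core import CoreSite

#: orientation -> forward-strand pattern pairs (lut_at_p, lut_at_p+4+spacer),
#: including the reverse complement of the whole configuration
_ORIENT_PATTERNS = {
    "FF": (("f1", "f2"), ("r2", "r1")),
    "FR": (("f1", "r2"), ("f2", "r1")),
    "RF": (("r1", "f2"), ("r2", "f1")),
}


def _luts(consensus1: str, consensus2: str, mismatches: int):
    f1 = site_lut(consensus1, mismatches)
    f2 = site_lut(consensus2, mismatches)
    return {"f1": f1, "f2": f2, "r1": rc_lut(f1), "r2": rc_lut(f2)}


def config_position_matrix(
    words: np.ndarray,
    consensus1: str,
    consensus2: str,
    spacer: int,
    orientation: str = "FF",
    mismatches: int = 0,
) -> np.ndarray:
    """Boolean (n_reads, n_start_positions) matrix of configuration placements.

    A placement and its full reverse complement are the same event: the two
    strand-patterns are OR-ed at each start position.
    """
    if orientation not in _ORIENT_PATTERNS:
        raise ValueError(f"invalid orientation {orientation!r}")
    luts = _luts(consensus1, consensus2, mismatches)
    n, n_pos = words.shape
    gap = 4 + spacer
    width = n_pos - gap
    if width <= 0:
        return np.zeros((n, 0), dtype=bool)
    out = np.zeros((n, width), dtype=bool)
    seen = set()
    for pa, pb in _ORIENT_PATTERNS[orientation]:
        key = (pa, pb)
        if key in seen:
            continue
        seen.add(key)
        out |= luts[pa][words[:, :width]] & luts[pb][words[:, gap:]]
    return out


def dimer_read_mask(dimer: DimerModel, words: np.ndarray, mismatches: int = 0) -> np.ndarray:
    hits = config_position_matrix(
        words,
        dimer.site1.consensus,
        dimer.site2.consensus,
        dimer.spacer,
        dimer.orientation,
        mismatches,
    )
    return hits.any(axis=1) if hits.size else np.zeros(words.shape[0], dtype=bool)


def count_dimer_reads(dimer: DimerModel, reads, mismatches: int = 0):
    """(count, fraction) of reads containing >=1 full dimer configuration."""
    if not len(reads):
        raise ValueError("read pool is empty")
    words = word_matrix(encode_seqs(reads))
    mask = dimer_read_mask(dimer, words, mismatches)
    count = int(mask.sum())
    return count, count / len(reads)


def count_monomer_reads(site: CoreSite, dimer: DimerModel, reads, mismatches: int = 0):
    """(count, fraction) of dimer-free reads with >=1 core-site match (either strand)."""
    if not len(reads):
        raise ValueError("read pool is empty")
    words = word_matrix(encode_seqs(reads))
    dmask = dimer_read_mask(dimer, words, mismatches)
    slut = site_lut(site.consensus, mismatches, both_strands=True)
    smask = slut[words].any(axis=1) if words.size else np.zeros(len(reads), dtype=bool)
    count = int((smask & ~dmask).sum())
    return count, count / len(reads)


def ln_fold_change(fraction_c: float, fraction_0: float, pseudo: float = 0.0) -> float:
    """ln((fraction_c + pseudo) / (fraction_0 + pseudo))."""
    if fraction_0 + pseudo <= 0:
        raise ValueError("cycle-0 fraction plus pseudocount must be positive")
    if fraction_c + pseudo <= 0:
        raise ValueError("cycle fraction plus pseudocount must be positive")
    return math.log((fraction_c + pseudo) / (fraction_0 + pseudo))


def fit_enrichment_slope(points):
    """OLS slope of ln fold change on cycle index; returns (slope, r_squared)."""
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("at least 2 points are required for a slope fit")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.all(x == x[0]):
        raise ValueError("all cycle indices identical; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


def enrichment_factor(slope_dimer: float, slope_site1: float, slope_site2: float) -> float:
    """EF = dimer slope / mean monomer slope; NaN when the denominator is <= 0."""
    denom = 0.5 * (slope_site1 + slope_site2)
    if denom <= 0:
        return float("nan")
    return slope_dimer / denom


@dataclass
class EnrichmentCurve:
    """Per-cycle occurrence fractions, ln fold changes, slopes and EF."""

    cycles: list[int]
    dimer_fraction: list[float]
    monomer_fraction_site1: list[float]
    monomer_fraction_site2: list[float]
    ln_fc_dimer: list[float]
    ln_fc_site1: list[float]
    ln_fc_site2: list[float]
    slope_dimer: float
    slope_site1: float
    slope_site2: float
    r2_dimer: float
    r2_site1: float
    r2_site2: float
    enrichment_factor: float
    dimer_counts: list[int] = field(default_factory=list)
    dimer: DimerModel | None = None


def compute_enrichment_curve(
    dimer: DimerModel, cycle_set, mismatches: int = 0
) -> EnrichmentCurve:
    """Count dimer/monomer fractions per cycle and fit the three slopes.

    A pseudocount of 0.5/|pool| per cycle guards the log against zero counts
    (cycle-0 counts of long configurations are frequently zero at 50k depth).
    """
    cycle_set.require_initial_library()
    cycles = cycle_set.cycle_indices
    fracs_d, fracs_1, fracs_2, counts_d, pseudos = [], [], [], [], []
    for c in cycles:
        reads = cycle_set.cycles[c]
        if not reads:
            raise ValueError(f"cycle {c} pool is empty")
        nd, fd = count_dimer_reads(dimer, reads, mismatches)
        _, f1 = count_monomer_reads(dimer.site1, dimer, reads, mismatches)
        _, f2 = count_monomer_reads(dimer.site2, dimer, reads, mismatches)
        fracs_d.append(fd)
        fracs_1.append(f1)
        fracs_2.append(f2)
        counts_d.append(nd)
        pseudos.append(0.5 / len(reads))

    def lfc(fracs):
        out = []
        for c, f, ps in zip(cycles, fracs, pseudos):
            if c == 0:
                out.append(0.0)
            else:
                out.append(math.log((f + ps) / (fracs[0] + pseudos[0])))
        return out

    lfc_d, lfc_1, lfc_2 = lfc(fracs_d), lfc(fracs_1), lfc(fracs_2)
    sd, r2d = fit_enrichment_slope(zip(cycles, lfc_d))
    s1, r21 = fit_enrichment_slope(zip(cycles, lfc_1))
    s2, r22 = fit_enrichment_slope(zip(cycles, lfc_2))
    return EnrichmentCurve(
        cycles=cycles,
        dimer_fraction=fracs_d,
        monomer_fraction_site1=fracs_1,
        monomer_fraction_site2=fracs_2,
        ln_fc_dimer=lfc_d,
        ln_fc_site1=lfc_1,
        ln_fc_site2=lfc_2,
        slope_dimer=sd,
        slope_site1=s1,
        slope_site2=s2,
        r2_dimer=r2d,
        r2_site1=r21,
        r2_site2=r22,
        enrichment_factor=enrichment_factor(sd, s1, s2),
        dimer_counts=counts_d,
        dimer=dimer,
    )
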