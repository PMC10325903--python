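"""Counting two-site configurations at every spacer length and orientation.

For each spacer s and orientation (FF head-to-tail, FR head-to-head,
RF tail-to-tail; RR folds into FF by reverse-complement equivalence) the
number of reads carrying at least one (site1, s, site2) configuration on
either strand is tabulated.  Spacer specificity is then tested with a
one-sided Grubbs max-outlier test on the final-cycle counts and a chi-square
test of independence between the initial library and the final cycle; a
spacer is called only when both reject (with a Bonferroni correction across
the orientations examined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._seq import encode_seqs, word_matrix
from .enrichment import config_position_matrix
from .motif_core import CoreSite

ORIENTATIONS = ("FF", "FR", "RF")


@dataclass
class SpacerCounts:
    """Per-(spacer, orientation) read counts with an observability mask."""

    spacers: np.ndarray                # (S,)
    orientations: tuple[str, ...]      # (O,)
    counts: np.ndarray                 # (S, O) int
    observable: np.ndarray             # (S,) bool; False = read length too short
    n_reads: int = 0

    def vector(self, orientation: str) -> np.ndarray:
        """Observable counts for one orientation."""
        o = self.orientations.index(orientation)
        return self.counts[self.observable, o]


@dataclass
class SpacerProfile:
    """Completed spacer-specificity result for one dimer model."""

    spacer_range: tuple[int, int]
    orientations: tuple[str, ...]
    counts_cycle0: SpacerCounts
    counts_cycle4: SpacerCounts
    grubbs_g: float
    grubbs_p: float
    chi2_stat: float
    chi2_p: float
    best_orientation: str | None
    called_spacer: int | None
    alpha: float = 0.05
    per_orientation: dict | None = None


def count_spacers(
    site1: CoreSite | str,
    site2: CoreSite | str,
    reads,
    spacer_range=(0, 20),
    orientations=ORIENTATIONS,
    mismatches: int = 0,
) -> SpacerCounts:
    """Count reads with >=1 two-site configuration per (spacer, orientation).

    A read contributes at most once per cell; a configuration and its full
    reverse complement are one event.  Spacers that cannot fit in the read
    length are flagged unobservable rather than zero-filled.
    """
    if not len(reads):
        raise ValueError("read pool is empty")
    c1 = site1.consensus if isinstance(site1, CoreSite) else str(site1).upper()
    c2 = site2.consensus if isinstance(site2, CoreSite) else str(site2).upper()
    lo, hi = spacer_range
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid spacer range {spacer_range}")
    arr = encode_seqs(reads)
    words = word_matrix(arr)
    max_len = max(len(r) for r in reads)
    spacers = np.arange(lo, hi + 1)
    counts = np.zeros((len(spacers), len(orientations)), dtype=int)
    observable = (spacers + 8) <= max_len
    for si, s in enumerate(spacers):
        if not observable[si]:
            continue
        for oi, orient in enumerate(orientations):
            hits = config_position_matrix(words, c1, c2, int(s), orient, mismatches)
            counts[si, oi] = int(hits.any(axis=1).sum()) if hits.size else 0
    return SpacerCounts(
        spacers=spacers,
        orientations=tuple(orientations),
        counts=counts,
        observable=observable,
        n_reads=len(reads),
    )


def count_spacers_in_regions(
    site1, site2, regions, spacer_range=(0, 20), orientations=ORIENTATIONS,
    mismatches: int = 0,
) -> SpacerCounts:
    """Identical counting semantics applied to peak-region sequences."""
    if not regions.sequences:
        raise ValueError("region set has no sequences")
    return count_spacers(
        site1, site2, regions.sequences, spacer_range, orientations, mismatches
    )


def grubbs_max_test(counts) -> tuple[float, float]:
    """One-sided Grubbs test for a single maximum outlier.

    G = (max - mean) / sd; the p-value follows the classical t-distribution
    form with n-2 degrees of freedom, capped at 1.  A zero-variance vector
    returns (0, 1).
    """
    x = np.asarray(counts, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 cells")
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0, 1.0
    g = float((x.max() - x.mean()) / sd)
    if g <= 0:
        return g, 1.0
    denom = (n - 1) ** 2 - n * g * g
    if denom <= 0:
        return g, 0.0
    t = np.sqrt(n * (n - 2) * g * g / denom)
    p = n * stats.t.sf(t, n - 2)
    return g, float(min(1.0, p))


def _pool_low_expected(c0: np.ndarray, c4: np.ndarray, min_expected: float = 1.0):
    """Pool adjacent cells toward the center until all expected counts >= 1."""
    groups = [[i] for i in range(len(c0))]
    a = c0.astype(float).copy()
    b = c4.astype(float).copy()
    while len(a) > 2:
        total = a.sum() + b.sum()
        row0, row1 = a.sum(), b.sum()
        col = a + b
        expected = np.concatenate([row0 * col / total, row1 * col / total])
        if expected.min() >= min_expected:
            break
        k = int(np.argmin(a + b))  # weakest column drives the low expectation
        center = (len(a) - 1) / 2
        j = k + 1 if k < center else k - 1
        lo, hi = min(j, k), max(j, k)
        a[lo] += a[hi]
        b[lo] += b[hi]
        groups[lo] = groups[lo] + groups[hi]
        a = np.delete(a, hi)
        b = np.delete(b, hi)
        del groups[hi]
    return a, b, groups


def chi_square_independence(counts_cycle0, counts_cycle4) -> tuple[float, float]:
    """2 x K chi-square test of cycle-by-spacer independence.

    Expected counts come from the margins; cells with expected < 1 are pooled
    into a neighbor toward the center of the spacer range before testing.
    dof = K' - 1 after pooling.
    """
    c0 = np.asarray(counts_cycle0, dtype=float)
    c4 = np.asarray(counts_cycle4, dtype=float)
    if c0.shape != c4.shape:
        raise ValueError("count vectors must cover the same spacer cells")
    if c0.sum() == 0 or c4.sum() == 0:
        raise ValueError("all counts zero in one cycle; test undefined")
    a, b, _ = _pool_low_expected(c0, c4)
    obs = np.vstack([a, b])
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    keep = expected[0] > 0
    chi2 = float(((obs[:, keep] - expected[:, keep]) ** 2 / expected[:, keep]).sum())
    dof = int(keep.sum()) - 1
    if dof <= 0:
        return chi2, 1.0
    return chi2, float(stats.chi2.sf(chi2, dof))


def call_spacer_specificity(
    counts_cycle0: SpacerCounts,
    counts_cycle4: SpacerCounts,
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> SpacerProfile:
    """Run both spacer-specificity tests and call a spacer when both reject.

    Tests run per orientation; the orientation with the smallest Grubbs p is
    reported, with p-values Bonferroni-adjusted for the number of
    orientations examined.  The called spacer is the argmax cell of the
    final-cycle counts, present only when both adjusted p-values < alpha.
    """
    if not np.array_equal(counts_cycle0.spacers, counts_cycle4.spacers):
        raise ValueError("profiles are not aligned on the same spacer cells")
    orientations = counts_cycle0.orientations
    n_orient = len(orientations) if bonferroni else 1
    per = {}
    best = None
    for orient in orientations:
        v0 = counts_cycle0.vector(orient)
        v4 = counts_cycle4.vector(orient)
        g, gp = grubbs_max_test(v4)
        try:
            chi2, cp = chi_square_independence(v0, v4)
        except ValueError:
            chi2, cp = 0.0, 1.0
        gp_adj = min(1.0, gp * n_orient)
        cp_adj = min(1.0, cp * n_orient)
        spacers = counts_cycle4.spacers[counts_cycle4.observable]
        argmax_spacer = int(spacers[np.argmax(v4)]) if v4.size else None
        per[orient] = {
            "grubbs_g": g, "grubbs_p": gp_adj, "chi2_stat": chi2,
            "chi2_p": cp_adj, "argmax_spacer": argmax_spacer,
        }
        if best is None or gp_adj < per[best]["grubbs_p"]:
            best = orient
    b = per[best]
    called = (
        b["argmax_spacer"]
        if b["grubbs_p"] < alpha and b["chi2_p"] < alpha
        else None
    )
    lo = int(counts_cycle0.spacers[0])
    hi = int(counts_cycle0.spacers[-1])
    return SpacerProfile(
        spacer_range=(lo, hi),
        orientations=orientations,
        counts_cycle0=counts_cycle0,
        counts_cycle4=counts_cycle4,
        grubbs_g=b["grubbs_g"],
        grubbs_p=b["grubbs_p"],
        chi2_stat=b["chi2_stat"],
        chi2_p=b["chi2_p"],
        best_orientation=best,
        called_spacer=called,
        alpha=alpha,
        per_orientation=per,
    )


def plot_spacer_profile(profile: SpacerProfile, path=None):
    """Per-spacer bar plot of final-cycle counts for the best orientation."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    orient = profile.best_orientation or profile.orientations[0]
    c4 = profile.counts_cycle4
    spacers = c4.spacers[c4.observable]
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(spacers, c4.vector(orient), color="steelblue")
    ax.set_xlabel("spacer length (bp)")
    ax.set_ylabel("reads with configuration")
    ax.set_title(f"orientation {orient}, Grubbs p={profile.grubbs_p:.3g}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
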