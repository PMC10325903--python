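"""Cooperativity quantification (Tau) from EMSA band proportions.

An EMSA lane resolves a two-site probe into three bands: unbound probe [D],
monomer-bound [PD] and dimer-bound [P2D].  The Tau factor

    tau = 4 [P2D] [D] / [PD]^2

is the fold-facilitation of the second binding event (the coefficient
relating K_d2 to K_d1).  Tau = 1 is independent binding: for per-site
occupancy p the proportions are (p^2, 2p(1-p), (1-p)^2) and the 4 cancels
the binomial factor exactly.  The dissociation constants themselves are
never estimated here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class EmsaLane:
    """One quantified binding reaction (proportions sum to 1)."""

    probe_id: str
    replicate: int
    protein_conc: float  # nM
    p2d: float           # proportion bound as dimer
    pd: float            # proportion bound as monomer
    d: float             # proportion unbound

    def __post_init__(self):
        for name, v in (("p2d", self.p2d), ("pd", self.pd), ("d", self.d)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.p2d + self.pd + self.d
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"band proportions sum to {total:.8f}, not 1")


@dataclass
class TauResult:
    per_lane_tau: list[float]
    mean_tau: float
    sd_tau: float
    n: int
    n_excluded: int = 0


def normalize_band_intensities(i_p2d: float, i_pd: float, i_d: float):
    """Convert raw band intensities of one lane to proportions."""
    total = i_p2d + i_pd + i_d
    if total <= 0:
        raise ValueError("total band intensity must be positive")
    return i_p2d / total, i_pd / total, i_d / total


def compute_tau(lane: EmsaLane) -> float:
    """tau = 4 * [P2D] * [D] / [PD]^2; undefined (NaN) when [PD] = 0."""
    if lane.pd == 0:
        return float("nan")
    return 4.0 * lane.p2d * lane.d / (lane.pd**2)


def summarize_tau(lanes, pd_floor: float = 0.01) -> TauResult:
    """Mean and sample SD of tau over valid lanes.

    Lanes with a monomer band below `pd_floor` are excluded (tau diverges as
    [PD] -> 0) and reported via `n_excluded`.
    """
    taus, excluded = [], 0
    for lane in lanes:
        if lane.pd < pd_floor:
            excluded += 1
            continue
        taus.append(compute_tau(lane))
    if not taus:
        raise ValueError("no valid lanes (all monomer bands below the floor)")
    arr = np.asarray(taus)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return TauResult(
        per_lane_tau=[float(t) for t in taus],
        mean_tau=float(arr.mean()),
        sd_tau=sd,
        n=len(taus),
        n_excluded=excluded,
    )


def compare_tau(group_a, group_b, equal_var: bool = True) -> float:
    """Two-sided unpaired Student t-test p-value between two tau groups.

    Equal-variance by default; set ``equal_var=False`` for Welch's variant.
    Two constant, identical groups return p = 1.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(res.pvalue)
    return p if not math.isnan(p) else 1.0


def read_emsa_lanes(path, normalize: bool = False) -> list[EmsaLane]:
    """Read lanes from a delimited table.

    Columns: probe_id, replicate, protein_conc_nM, p2d, pd, d — proportions
    by default, raw band intensities with ``normalize=True``.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    required = ["probe_id", "replicate", "protein_conc_nM", "p2d", "pd", "d"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    lanes = []
    for _, row in df.iterrows():
        p2d, pd_, d = float(row["p2d"]), float(row["pd"]), float(row["d"])
        if normalize:
            p2d, pd_, d = normalize_band_intensities(p2d, pd_, d)
        lanes.append(
            EmsaLane(
                probe_id=str(row["probe_id"]),
                replicate=int(row["replicate"]),
                protein_conc=float(row["protein_conc_nM"]),
                p2d=p2d, pd=pd_, d=d,
            )
        )
    return lanes
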