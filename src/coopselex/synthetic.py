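"""Synthetic HT-SELEX and EMSA generators with known ground truth.

The SELEX simulator draws a random fixed-length oligo library and runs
rounds of binding-probability-weighted selection followed by PCR-style
multinomial resampling.  Each read's selection weight is

    w = 1 + monomer_weight * (m1 + m2) + monomer_weight * omega * d

where m1/m2 count matches to the two core sites outside planted-spacer
configurations and d counts planted-spacer dimer configurations.  With
omega = 1 a dimer configuration confers exactly the advantage of a single
binding event, so dimer and monomer site fractions enrich at the same rate
(EF -> 1); omega > 1 is the fold advantage of the paired configuration and
drives the faster dimer enrichment the pipeline detects.

The EMSA simulator produces band proportions from the two-step equilibrium
with K_d2 = K_d1 / omega:  D : PD : P2D  =  1 : 2a : omega a^2  with
a = [P]/K_d1, so the noiseless lanes satisfy tau = omega identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import decode_seqs, site_lut, word_matrix
from .enrichment import config_position_matrix
from .selex_io import SelexCycleSet
from .tau_emsa import EmsaLane


@dataclass
class SelexSimParams:
    """Ground-truth parameters for a simulated SELEX experiment."""

    library_size: int = 50_000
    population_size: int | None = None  # physical pool depth; default 10x library
    read_length: int = 20
    n_cycles: int = 4
    site_consensus1: str = "TAAT"
    site_consensus2: str = "TAAT"
    planted_spacer: int = 7
    orientation: str = "FF"
    monomer_weight: float = 5.0
    omega: float = 1.0
    selection_stringency: float = 0.2
    amplification_noise: bool = True
    mismatches: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if not 0 < self.selection_stringency <= 1:
            raise ValueError("selection stringency must be in (0, 1]")
        if self.read_length < 8 + self.planted_spacer:
            raise ValueError("read length too short for the planted configuration")
        if self.orientation not in ("FF", "FR", "RF"):
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if self.population_size is None:
            self.population_size = 10 * self.library_size
        if self.population_size < self.library_size:
            raise ValueError("population_size must be >= library_size")


def generate_initial_library(params: SelexSimParams, rng=None) -> np.ndarray:
    """Encoded (n, L) uint8 pool of iid uniform-base sequences."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    return rng.integers(0, 4, size=(params.library_size, params.read_length),
                        dtype=np.uint8)


def _initial_population(params: SelexSimParams, rng) -> np.ndarray:
    return rng.integers(0, 4, size=(params.population_size, params.read_length),
                        dtype=np.uint8)


def _binding_weights(pool: np.ndarray, params: SelexSimParams) -> np.ndarray:
    """Per-read binding weight w = 1 + mw*(monomer sites) + mw*omega*(configs).

    Monomer sites are counted as a maximal set of mutually non-overlapping
    matches (a 4-bp site and its reverse-strand reading are one binding
    surface) lying entirely outside any planted-configuration footprint —
    overlapping proteins cannot bind simultaneously.
    """
    words = word_matrix(pool)
    n, n_pos = words.shape
    cfg = config_position_matrix(
        words, params.site_consensus1, params.site_consensus2,
        params.planted_spacer, params.orientation, params.mismatches,
    )
    d = cfg.sum(axis=1) if cfg.size else np.zeros(n)
    # occlude every site start position overlapping a configuration footprint
    occluded = np.zeros((n, n_pos), dtype=bool)
    if cfg.size:
        gap = 4 + params.planted_spacer
        width = cfg.shape[1]
        for off in range(-3, gap + 4):
            lo = max(0, off)
            hi = min(n_pos, width + off)
            if hi > lo:
                occluded[:, lo:hi] |= cfg[:, lo - off : hi - off]
    hits = np.zeros((n, n_pos), dtype=bool)
    for cons in {params.site_consensus1, params.site_consensus2}:
        lut = site_lut(cons, params.mismatches, both_strands=True)
        hits |= lut[words]
    hits &= ~occluded
    # greedy left-to-right maximum non-overlapping match count
    m = np.zeros(n)
    last_end = np.full(n, -1)
    for p in range(n_pos):
        take = hits[:, p] & (last_end <= p - 1)
        m += take
        last_end[take] = p + 3
    return 1.0 + params.monomer_weight * m + params.monomer_weight * params.omega * d


def simulate_selection_round(pool: np.ndarray, params: SelexSimParams, rng) -> np.ndarray:
    """One round: weighted retention of a pool fraction, then PCR resampling."""
    if pool.shape[0] == 0:
        raise ValueError("empty pool")
    w = _binding_weights(pool, params)
    if not np.any(w > 0):
        raise ValueError("all binding weights zero; degenerate parameters")
    size = pool.shape[0]
    k = int(np.ceil(params.selection_stringency * size))
    # Gumbel top-k = weighted sampling without replacement (exponential race)
    keys = np.log(w) + rng.gumbel(size=w.shape)
    kept = np.argpartition(keys, -k)[-k:]
    if params.amplification_noise:
        amplified = rng.integers(0, k, size=size)
        return pool[kept[amplified]]
    reps = int(np.ceil(size / k))
    out = np.tile(pool[kept], (reps, 1))[:size]
    return out


def simulate_selex(params: SelexSimParams) -> SelexCycleSet:
    """Chain the initial library and n_cycles selection rounds.

    The physical pool carries `population_size` molecules (emulating the
    molecular diversity of a real library, which vastly exceeds sequencing
    depth); each cycle's returned read pool is a fresh `library_size`
    subsample of it, mirroring how deep sequencing samples a SELEX round.
    """
    rng = np.random.default_rng(params.seed)
    pool = _initial_population(params, rng)

    def observe(p):
        if params.population_size == params.library_size:
            return decode_seqs(p)
        idx = rng.choice(p.shape[0], size=params.library_size, replace=False)
        return decode_seqs(p[idx])

    cycles = {0: observe(pool)}
    for c in range(1, params.n_cycles + 1):
        pool = simulate_selection_round(pool, params, rng)
        cycles[c] = observe(pool)
    return SelexCycleSet(
        cycles=cycles,
        source=f"synthetic omega={params.omega} spacer={params.planted_spacer} "
               f"orient={params.orientation} seed={params.seed}",
    )


def dimer_read_fraction(pool_seqs, params: SelexSimParams) -> float:
    """Ground-truth fraction of reads carrying the planted configuration."""
    from ._seq import encode_seqs

    words = word_matrix(encode_seqs(pool_seqs))
    cfg = config_position_matrix(
        words, params.site_consensus1, params.site_consensus2,
        params.planted_spacer, params.orientation, params.mismatches,
    )
    if not cfg.size:
        return 0.0
    return float(cfg.any(axis=1).mean())


def planted_dimer_model(params: SelexSimParams):
    """The ground-truth DimerModel a simulation was generated from."""
    from .dimer_select import DimerModel
    from .motif_core import CoreSite, consensus_to_pwm

    def core(cons, offset):
        pwm = consensus_to_pwm(cons, params.mismatches)
        return CoreSite(
            pwm4=pwm, offset=offset, consensus=cons.upper(),
            mean_ic=float(pwm.information_content().mean()),
        )

    return DimerModel(
        site1=core(params.site_consensus1, 0),
        site2=core(params.site_consensus2, 4 + params.planted_spacer),
        spacer=params.planted_spacer,
        orientation=params.orientation,
    )


def simulate_emsa_lanes(
    kd1: float,
    omega: float,
    protein_concs,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    probe_id: str = "probe",
) -> list[EmsaLane]:
    """Equilibrium band proportions for a two-site probe titration.

    Proportions are D : PD : P2D = 1 : 2a : omega a^2 (a = [P]/kd1),
    normalized per lane; Gaussian noise of sd `noise_sd` is added to the
    proportions, clipped to [0, 1] and renormalized.
    """
    if kd1 <= 0:
        raise ValueError("kd1 must be positive")
    if omega <= 0:
        raise ValueError("omega must be positive")
    rng = np.random.default_rng(seed)
    lanes = []
    for conc in protein_concs:
        a = conc / kd1
        raw = np.array([omega * a * a, 2.0 * a, 1.0])  # P2D, PD, D
        props = raw / raw.sum()
        for rep in range(1, n_replicates + 1):
            p = props.copy()
            if noise_sd > 0:
                p = np.clip(p + rng.normal(0.0, noise_sd, size=3), 0.0, None)
                if p.sum() == 0:
                    p = props.copy()
                p = p / p.sum()
            lanes.append(
                EmsaLane(
                    probe_id=probe_id,
                    replicate=rep,
                    protein_conc=float(conc),
                    p2d=float(p[0]),
                    pd=float(p[1]),
                    d=float(p[2]),
                )
            )
    return lanes
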