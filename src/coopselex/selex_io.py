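"""Reading and writing the external formats around the pipeline.

Covers per-cycle HT-SELEX read pools (FASTA/FASTQ via Bio.SeqIO), the Homer
``.motif`` dialect, JASPAR PFM output, BED + genome FASTA region extraction,
and reproducible subsampling of read pools.  BED coordinates are 0-based
half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .motif_core import PWM

_VALID = set("ACGTN")


@dataclass
class SelexCycleSet:
    """Per-cycle read pools: cycle 0 is the unselected library."""

    cycles: dict[int, list[str]]
    source: str = ""
    subsample_seed: int | None = None

    def __post_init__(self):
        if any(c < 0 for c in self.cycles):
            raise ValueError("cycle indices must be >= 0")
        self.cycles = dict(sorted(self.cycles.items()))

    @property
    def cycle_indices(self) -> list[int]:
        return list(self.cycles)

    @property
    def read_length(self) -> int:
        for reads in self.cycles.values():
            if reads:
                return len(reads[0])
        return 0

    def require_initial_library(self):
        if 0 not in self.cycles:
            raise ValueError("initial library required: cycle 0 is missing")
        if len(self.cycles) < 2:
            raise ValueError("at least 2 cycles are required for a slope fit")


@dataclass
class RegionSet:
    """Genomic intervals (0-based half-open) with their extracted sequences."""

    intervals: list[tuple[str, int, int]]
    sequences: list[str] = field(default_factory=list)

    def __post_init__(self):
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
        if self.sequences and len(self.sequences) != len(self.intervals):
            raise ValueError("sequence/interval count mismatch")
        for (c, s, e), seq in zip(self.intervals, self.sequences):
            if len(seq) != e - s:
                raise ValueError(f"sequence length != interval span for {c}:{s}-{e}")


def read_cycle_reads(path, format: str = "fasta") -> list[str]:
    """Read a pool of sequences; qualities are discarded for FASTQ."""
    path = Path(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    reads = []
    for i, rec in enumerate(SeqIO.parse(str(path), format)):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(
                f"record {i} ({rec.id}): invalid characters {sorted(bad)}"
            )
        reads.append(seq)
    if not reads:
        raise ValueError(f"no records parsed from {path}")
    return reads


def write_fasta(reads, path, prefix: str = "read"):
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f">{prefix}_{i}\n{seq}\n")


def subsample_reads(reads, n: int, seed: int) -> list[str]:
    """Uniform subsample without replacement, reproducible under `seed`."""
    if n <= 0:
        raise ValueError("subsample size must be >= 1")
    if n >= len(reads):
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in idx]


def read_homer_motif(path) -> list[PWM]:
    """Parse a Homer ``.motif`` file (possibly multi-motif).

    Header: ``>CONSENSUS<TAB>NAME<TAB>LOG_ODDS_THRESHOLD`` then one line per
    position with 4 probabilities in A,C,G,T order.  Rows are renormalized on
    load (Homer writes rounded values).
    """
    motifs = []
    header = None
    rows: list[list[float]] = []

    def flush():
        if header is None:
            return
        if not rows:
            raise ValueError(f"motif {header[1]!r} has no probability rows")
        motifs.append(
            PWM(np.asarray(rows), name=header[1], score_threshold=header[2])
        )

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split("\t")
                if len(parts) < 3:
                    raise ValueError(f"line {lineno}: malformed Homer header")
                header = (parts[0], parts[1], float(parts[2]))
                rows = []
            else:
                fields = line.split()
                if len(fields) != 4:
                    raise ValueError(
                        f"line {lineno}: expected 4 probabilities, got {len(fields)}"
                    )
                vals = [float(v) for v in fields]
                total = sum(vals)
                if not 0.9 <= total <= 1.1:
                    raise ValueError(
                        f"line {lineno}: probabilities sum to {total:.4g}, "
                        "outside [0.9, 1.1]"
                    )
                rows.append(vals)
    flush()
    if not motifs:
        raise ValueError(f"no motifs parsed from {path}")
    return motifs


def write_homer_motif(pwms, path):
    """Write PWMs in the Homer ``.motif`` dialect."""
    if isinstance(pwms, PWM):
        pwms = [pwms]
    with open(path, "w") as fh:
        for pwm in pwms:
            thr = pwm.score_threshold if pwm.score_threshold is not None else 0.0
            fh.write(f">{pwm.consensus}\t{pwm.name or pwm.consensus}\t{thr:.6f}\n")
            for row in pwm.probs:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def write_jaspar_pfm(pwm: PWM, counts_scale: int, path):
    """Write a PWM as a JASPAR PFM (counts = round(prob * counts_scale))."""
    counts = np.rint(pwm.probs * counts_scale).astype(int)
    width = max(len(str(v)) for v in counts.ravel())
    with open(path, "w") as fh:
        fh.write(f">{pwm.name or pwm.consensus}\n")
        for bi, base in enumerate("ACGT"):
            row = " ".join(f"{counts[j, bi]:>{width}d}" for j in range(pwm.length))
            fh.write(f"{base} [ {row} ]\n")


def read_jaspar_pfm(path) -> list[PWM]:
    """Read JASPAR PFM(s) back into probability PWMs (via Bio.motifs)."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
            out.append(PWM(counts, name=m.name or ""))
    return out


def extract_region_sequences(bed_path, fasta_path) -> RegionSet:
    """Extract BED interval sequences from a genome FASTA (0-based half-open)."""
    genome = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    intervals = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"BED line {lineno}: empty interval {start}-{end}")
            if chrom not in genome:
                raise ValueError(f"chromosome {chrom!r} absent from FASTA")
            if end > len(genome[chrom]):
                raise ValueError(
                    f"interval {chrom}:{start}-{end} beyond contig end "
                    f"({len(genome[chrom])} bp)"
                )
            intervals.append((chrom, start, end))
    sequences = [genome[c][s:e] for c, s, e in intervals]
    return RegionSet(intervals=intervals, sequences=sequences)
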