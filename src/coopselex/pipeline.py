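"""End-to-end orchestration: reads -> screen -> enrichment -> spacing -> call.

`run_pipeline` consumes a `RunConfig` (or a ready `SelexCycleSet`), screens
every candidate long motif (imported Homer motifs or internal discovery),
and writes a JSON + TSV report with every intermediate value, the full
configuration and the seed, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .decision import classify_cooperativity
from .dimer_select import discover_long_motifs, screen_dimer
from .enrichment import compute_enrichment_curve
from .selex_io import SelexCycleSet, read_cycle_reads, read_homer_motif, subsample_reads
from .spacing import ORIENTATIONS, call_spacer_specificity, count_spacers

logger = logging.getLogger("coopselex")


@dataclass
class RunConfig:
    """Inputs and thresholds for one pipeline run."""

    tf_name: str = "TF"
    cycle_paths: dict = field(default_factory=dict)   # cycle index -> path
    read_format: str = "fasta"
    motif_file: str | None = None                     # Homer .motif; else discovery
    ic_min: float = 0.6
    flank_ratio_min: float = 1.5
    abundance_min: float = 0.05
    ef_min: float = 2.0
    alpha: float = 0.05
    spacer_range: tuple = (0, 20)
    orientations: tuple = ORIENTATIONS
    mismatches: int = 0
    surround: str = "pooled"
    discovery_top_k: int = 3
    subsample: int | None = 50_000
    seed: int = 1
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cycle_paths" in raw:
            raw["cycle_paths"] = {int(k): v for k, v in raw["cycle_paths"].items()}
        for key in ("spacer_range", "orientations"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_cycles(config: RunConfig) -> SelexCycleSet:
    cycles = {
        c: read_cycle_reads(p, config.read_format)
        for c, p in sorted(config.cycle_paths.items())
    }
    return SelexCycleSet(cycles=cycles, source=str(config.cycle_paths))


def _round6(x):
    if isinstance(x, float):
        return round(x, 6)
    if isinstance(x, list):
        return [_round6(v) for v in x]
    return x


def run_pipeline(config: RunConfig, cycle_set: SelexCycleSet | None = None) -> dict:
    """Run the full cooperativity prediction for one TF; returns the report dict."""
    if cycle_set is None:
        cycle_set = _load_cycles(config)
    cycle_set.require_initial_library()
    if config.subsample:
        cycle_set = SelexCycleSet(
            cycles={
                c: subsample_reads(reads, config.subsample, config.seed)
                for c, reads in cycle_set.cycles.items()
            },
            source=cycle_set.source,
            subsample_seed=config.seed,
        )
    last = max(cycle_set.cycle_indices)
    reads4 = cycle_set.cycles[last]
    reads0 = cycle_set.cycles[0]
    logger.info("cycles %s, %d reads in final cycle", cycle_set.cycle_indices, len(reads4))

    if config.motif_file:
        motifs = read_homer_motif(config.motif_file)
        logger.info("imported %d Homer motifs", len(motifs))
    else:
        motifs = discover_long_motifs(reads4, reads0, top_k=config.discovery_top_k)
        logger.info("internal discovery produced %d motifs", len(motifs))

    model_reports = []
    for mi, motif in enumerate(motifs):
        screen = screen_dimer(
            motif, reads4,
            ic_min=config.ic_min,
            flank_ratio_min=config.flank_ratio_min,
            abundance_min=config.abundance_min,
            surround=config.surround,
        )
        entry = {
            "motif_index": mi,
            "motif_name": motif.name,
            "motif_consensus": motif.consensus,
            "screen": {
                "ic_pass": screen.ic_pass,
                "flank_ratio_pass": screen.flank_ratio_pass,
                "abundance_pass": screen.abundance_pass,
                "site_ics": _round6(list(screen.site_ics)),
                "surround_ic": _round6(screen.surround_ic),
                "abundance": _round6(screen.abundance),
                "reasons": screen.reasons,
            },
        }
        if screen.candidate is None:
            entry["call"] = {"dimer_detected": False, "cooperative": False}
            model_reports.append(entry)
            continue
        dimer = screen.candidate
        curve = compute_enrichment_curve(dimer, cycle_set, config.mismatches)
        counts0 = count_spacers(
            dimer.site1, dimer.site2, reads0, config.spacer_range,
            config.orientations, config.mismatches,
        )
        counts4 = count_spacers(
            dimer.site1, dimer.site2, reads4, config.spacer_range,
            config.orientations, config.mismatches,
        )
        profile = call_spacer_specificity(counts0, counts4, alpha=config.alpha)
        call = classify_cooperativity(
            screen, curve, profile, tf_name=config.tf_name,
            ef_min=config.ef_min, alpha=config.alpha,
        )
        entry["dimer"] = {
            "site1": dimer.site1.consensus,
            "site2": dimer.site2.consensus,
            "spacer": dimer.spacer,
            "orientation": dimer.orientation,
        }
        entry["enrichment"] = {
            "cycles": curve.cycles,
            "dimer_fraction": _round6(curve.dimer_fraction),
            "monomer_fraction_site1": _round6(curve.monomer_fraction_site1),
            "monomer_fraction_site2": _round6(curve.monomer_fraction_site2),
            "ln_fc_dimer": _round6(curve.ln_fc_dimer),
            "ln_fc_site1": _round6(curve.ln_fc_site1),
            "ln_fc_site2": _round6(curve.ln_fc_site2),
            "slope_dimer": _round6(curve.slope_dimer),
            "slope_site1": _round6(curve.slope_site1),
            "slope_site2": _round6(curve.slope_site2),
            "r2_dimer": _round6(curve.r2_dimer),
            "enrichment_factor": _round6(curve.enrichment_factor),
        }
        entry["spacing"] = {
            "best_orientation": profile.best_orientation,
            "grubbs_g": _round6(profile.grubbs_g),
            "grubbs_p": _round6(profile.grubbs_p),
            "chi2_stat": _round6(profile.chi2_stat),
            "chi2_p": _round6(profile.chi2_p),
            "called_spacer": profile.called_spacer,
            "counts_cycle4": {
                o: counts4.vector(o).tolist() for o in counts4.orientations
            },
            "observable_spacers": counts4.spacers[counts4.observable].tolist(),
        }
        entry["call"] = {
            "dimer_detected": True,
            "ef": _round6(call.ef),
            "ef_pass": call.ef_pass,
            "cooperative": call.cooperative,
        }
        model_reports.append(entry)

    cooperative = any(m["call"]["cooperative"] for m in model_reports)
    report = {
        "tf_name": config.tf_name,
        "coopselex_version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "n_motifs": len(motifs),
        "models": model_reports,
        "cooperative": cooperative,
    }
    if config.outdir:
        _write_report(report, Path(config.outdir))
    return report


def _write_report(report: dict, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    cols = [
        "tf_name", "motif_index", "site1", "site2", "spacer", "orientation",
        "ef", "grubbs_p", "chi2_p", "called_spacer", "cooperative",
    ]
    lines = ["\t".join(cols)]
    for m in report["models"]:
        dim = m.get("dimer", {})
        enr = m.get("enrichment", {})
        spc = m.get("spacing", {})
        row = [
            report["tf_name"], str(m["motif_index"]),
            dim.get("site1", "."), dim.get("site2", "."),
            str(dim.get("spacer", ".")), dim.get("orientation", "."),
            str(enr.get("enrichment_factor", ".")),
            str(spc.get("grubbs_p", ".")), str(spc.get("chi2_p", ".")),
            str(spc.get("called_spacer", ".")),
            str(m["call"]["cooperative"]),
        ]
        lines.append("\t".join(row))
    (outdir / "report.tsv").write_text("\n".join(lines) + "\n")
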