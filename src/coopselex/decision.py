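"""Final cooperative / non-cooperative call per transcription factor.

The call is a pure conjunction: a dimer site must survive the motif screen,
the enrichment factor must exceed the positivity threshold (default 2), and
both spacer-specificity tests must reject (default alpha 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .dimer_select import DimerScreenResult
from .enrichment import EnrichmentCurve
from .spacing import SpacerProfile


@dataclass
class CooperativityCall:
    tf_name: str
    dimer_detected: bool
    ef: float | None
    ef_pass: bool
    grubbs_p: float | None
    chi2_p: float | None
    spacer_called: int | None
    cooperative: bool


def classify_cooperativity(
    screen: DimerScreenResult | None,
    curve: EnrichmentCurve | None,
    profile: SpacerProfile | None,
    tf_name: str = "",
    ef_min: float = 2.0,
    alpha: float = 0.05,
) -> CooperativityCall:
    """Combine screening, enrichment and spacing evidence into one call."""
    dimer_detected = screen is not None and screen.candidate is not None
    if not dimer_detected:
        return CooperativityCall(
            tf_name=tf_name, dimer_detected=False, ef=None, ef_pass=False,
            grubbs_p=None, chi2_p=None, spacer_called=None, cooperative=False,
        )
    if curve is None or profile is None:
        raise ValueError("enrichment curve and spacer profile required after a screen pass")
    if curve.dimer is not None and screen.candidate is not None:
        same = (
            curve.dimer.site1.consensus == screen.candidate.site1.consensus
            and curve.dimer.site2.consensus == screen.candidate.site2.consensus
            and curve.dimer.spacer == screen.candidate.spacer
        )
        if not same:
            raise ValueError("enrichment curve computed from a different dimer model")
    ef = curve.enrichment_factor
    ef_pass = (ef is not None) and (not math.isnan(ef)) and ef > ef_min
    cooperative = (
        ef_pass
        and profile.grubbs_p < alpha
        and profile.chi2_p < alpha
        and profile.called_spacer is not None
    )
    return CooperativityCall(
        tf_name=tf_name,
        dimer_detected=True,
        ef=ef,
        ef_pass=ef_pass,
        grubbs_p=profile.grubbs_p,
        chi2_p=profile.chi2_p,
        spacer_called=profile.called_spacer,
        cooperative=cooperative,
    )
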