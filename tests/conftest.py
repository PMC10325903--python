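import numpy as np
import pytest

from coopselex.dimer_select import DimerModel
from coopselex.motif_core import CoreSite, consensus_to_pwm


def make_core(consensus: str, offset: int = 0) -> CoreSite:
    pwm = consensus_to_pwm(consensus)
    return CoreSite(
        pwm4=pwm,
        offset=offset,
        consensus=consensus.upper(),
        mean_ic=float(pwm.information_content().mean()),
    )


def make_dimer(c1: str = "TAAT", c2: str = "TAAT", spacer: int = 7,
               orientation: str = "FF") -> DimerModel:
    return DimerModel(
        site1=make_core(c1, 0),
        site2=make_core(c2, 4 + spacer),
        spacer=spacer,
        orientation=orientation,
    )


def random_reads(n: int, length: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n, length))
    return ["".join("ACGT"[c] for c in row) for row in codes]


@pytest.fixture
def gsx2_like_pwm():
    """16-bp motif with near-fixed TAAT cores at offsets 0 and 11, spacer 7."""
    rows = []
    consensus = "TAAT" + "N" * 7 + "TAAT" + "N"
    for b in consensus:
        if b == "N":
            rows.append([0.25, 0.25, 0.25, 0.25])
        else:
            i = "ACGT".index(b)
            row = [0.01] * 4
            row[i] = 0.97
            rows.append(row)
    from coopselex.motif_core import PWM

    return PWM(np.asarray(rows), name="gsx2_like")
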