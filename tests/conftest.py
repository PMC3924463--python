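import numpy as np
import pytest

from ctgdiag import (
    CriteriaSet,
    CTGTrace,
    DecelEpisode,
    KeyPoint,
    Shoulder,
    UCCycle,
)


@pytest.fixture
def criteria():
    return CriteriaSet()


@pytest.fixture
def varied_trace():
    """A fully valid trace with enough sample-to-sample variation that no
    cleaning heuristic fires: FHR around 140 with a small oscillation, UC
    with gentle activity above tone."""
    n = 1200
    t = np.arange(n) / 2.0
    fhr = 140.0 + 3.0 * np.sin(2 * np.pi * t / 37.0)
    uc = 5.0 + 2.0 * (1 + np.sin(2 * np.pi * t / 95.0))
    return CTGTrace(fhr, uc, rate=2.0, label="varied")


def make_episode(
    *,
    b=140.0,
    ucs_t=100.0,
    uce_t=180.0,
    hrs_t=110.0,
    fall_s=45.0,
    depth=45.0,
    shoulder_height=None,
    shoulder_lag=None,
):
    """Construct a deceleration episode directly from its governing
    quantities (used for rule-level tests, bypassing extraction)."""
    hrp_t = hrs_t + fall_s
    hre_t = hrp_t + fall_s
    ucp_t = (ucs_t + uce_t) / 2.0
    cycle = UCCycle(
        ucs=KeyPoint(ucs_t, 5.0), ucp=KeyPoint(ucp_t, 60.0), uce=KeyPoint(uce_t, 5.0)
    )
    shoulder = None
    if shoulder_height is not None:
        hsp_t = max(hre_t, hrp_t) + 5.0
        hse_t = hsp_t + (shoulder_lag if shoulder_lag is not None else 15.0)
        # hse.t - hre.t is what the rule compares
        hse_t = hre_t + (shoulder_lag if shoulder_lag is not None else 15.0)
        hse_t = max(hse_t, hsp_t)
        shoulder = Shoulder(
            hsp=KeyPoint(hsp_t, b + shoulder_height), hse=KeyPoint(hse_t, b)
        )
    return DecelEpisode(
        hrs=KeyPoint(hrs_t, b),
        hrp=KeyPoint(hrp_t, b - depth),
        hre=KeyPoint(hre_t, b),
        b=b,
        cycle=cycle,
        shoulder=shoulder,
    )
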