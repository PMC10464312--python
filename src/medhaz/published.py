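"""Published decomposition estimates for US adults (pooled 1997-2014
national health-interview cohort linked to mortality follow-up through
2015), in additional deaths per 10,000 person-years relative to
non-Hispanic White adults.

These printed values serve two purposes: they anchor the magnitudes of
the synthetic generator's defaults, and they let the arithmetic
structure of the decomposition (total = direct + net indirect;
net indirect = sum of the per-mediator exposure and vulnerability
components) be checked against real published output. Printed numbers
are rounded to one decimal, so the identities can only be expected to
hold to one unit in the last printed digit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["PUBLISHED_DECOMPOSITION", "additivity_discrepancies"]

# (sex, contrast) -> component -> printed point estimate
PUBLISHED_DECOMPOSITION = {
    ("men", "black"): {
        "total": 21.7,
        "direct": 23.7,
        "net_indirect": -2.0,
        "exposure_alcohol": 1.4,
        "vulnerability_alcohol": -2.6,
        "exposure_smoking": -5.9,
        "vulnerability_smoking": 2.2,
        "exposure_bmi": 0.5,
        "vulnerability_bmi": -1.4,
        "exposure_activity": 4.6,
        "vulnerability_activity": -0.7,
    },
    ("women", "black"): {
        "total": 11.5,
        "direct": 17.1,
        "net_indirect": -5.6,
        "exposure_alcohol": 5.1,
        "vulnerability_alcohol": -4.5,
        "exposure_smoking": -10.4,
        "vulnerability_smoking": 1.0,
        "exposure_bmi": 0.8,
        "vulnerability_bmi": -3.7,
        "exposure_activity": 7.8,
        "vulnerability_activity": -1.7,
    },
    ("men", "hispanic"): {
        "total": 1.4,
        "direct": 5.1,
        "net_indirect": -3.6,
        "exposure_alcohol": -0.4,
        "vulnerability_alcohol": -0.7,
        "exposure_smoking": -12.0,
        "vulnerability_smoking": 6.4,
        "exposure_bmi": -1.9,
        "vulnerability_bmi": 1.3,
        "exposure_activity": 6.6,
        "vulnerability_activity": -2.9,
    },
    ("women", "hispanic"): {
        "total": -9.3,
        "direct": -8.9,
        "net_indirect": -0.4,
        "exposure_alcohol": 4.9,
        "vulnerability_alcohol": -2.9,
        "exposure_smoking": -17.0,
        "vulnerability_smoking": 11.7,
        "exposure_bmi": -1.4,
        "vulnerability_bmi": 1.8,
        "exposure_activity": 7.5,
        "vulnerability_activity": -5.0,
    },
}


def additivity_discrepancies() -> dict:
    """Reconstruction errors of the printed decomposition identities.

    For every (sex, contrast): |direct + net_indirect - total| and
    |sum of the eight per-mediator components - net_indirect|, both in
    deaths per 10,000 person-years on the printed one-decimal scale.
    """
    out = {}
    for key, comp in PUBLISHED_DECOMPOSITION.items():
        parts = [v for k, v in comp.items() if k.startswith(("exposure_", "vulnerability_"))]
        out[key] = {
            "total_identity": float(
                np.round(abs(comp["direct"] + comp["net_indirect"] - comp["total"]), 10)
            ),
            "net_indirect_identity": float(
                np.round(abs(sum(parts) - comp["net_indirect"]), 10)
            ),
        }
    return out
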