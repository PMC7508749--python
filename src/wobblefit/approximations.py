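"""Algebraic R1rho expressions for two-state exchange.

These closed forms are independent of the numerical Bloch-McConnell
integrator and serve as cross-checks: the no-exchange limit is exact, and
the Laguerre second-order (asymmetric-population) expression is accurate to
a few percent outside the slow-exchange/large-amplitude corner.
"""

from __future__ import annotations

import numpy as np

from .models import ExchangeModel, NucleusChannel, dw_to_angular

__all__ = ["r1rho_no_exchange", "r1rho_laguerre"]


def r1rho_no_exchange(r1: float, r2: float, theta_deg: float) -> float:
    """R1rho = R1 cos^2(theta) + R2 sin^2(theta) (no chemical exchange)."""
    th = np.radians(theta_deg)
    return r1 * np.cos(th) ** 2 + r2 * np.sin(th) ** 2


def r1rho_laguerre(model: ExchangeModel, channel: NucleusChannel,
                   power_hz: float, offset_hz: float) -> float:
    """Laguerre second-order approximation for two-state R1rho.

    Valid without the skewed-population restriction; the tilt angle is taken
    relative to the population-averaged offset.  All algebra here is written
    directly from the closed-form expression, with no call into the matrix
    machinery, so it can act as an oracle for the numerical routes.
    """
    if model.topology != "two_state":
        raise ValueError("Laguerre expression applies to two-state exchange only")
    pa, pb = model.p_a, model.p_b
    kex = model.kex_ab
    dw = dw_to_angular(model.dw_ppm(channel.id)[1], channel)
    omega1 = 2.0 * np.pi * power_hz
    omega_a = 2.0 * np.pi * offset_hz
    omega_b = omega_a + dw
    omega_bar = pa * omega_a + pb * omega_b

    wa2 = omega_a ** 2 + omega1 ** 2
    wb2 = omega_b ** 2 + omega1 ** 2
    we2 = omega_bar ** 2 + omega1 ** 2
    sin2 = omega1 ** 2 / we2
    cos2 = 1.0 - sin2

    num = pa * pb * dw ** 2 * kex
    den = (wa2 * wb2 / we2 + kex ** 2
           - sin2 * pa * pb * dw ** 2
           * (1.0 + 2.0 * kex ** 2 * (pa * wa2 + pb * wb2)
              / (wa2 * wb2 + we2 * kex ** 2)))
    rex = sin2 * num / den
    return float(channel.r1 * cos2 + channel.r2 * sin2 + rex)
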