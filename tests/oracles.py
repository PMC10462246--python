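"""Independent brute-force oracles used to certify closed-form results.

Nothing here imports the implementation paths under test beyond plain data.
"""

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid


def bladder_tiac_simulated(
    fu,
    lambda_bio,
    lambda_p: float,
    voiding_interval_h: float,
    steps_per_cycle: int = 4000,
    residual: float = 1e-12,
    max_cycles: int = 200_000,
) -> float:
    """Discrete fill/decay/void simulation of the urinary bladder.

    The bladder fills at rate sum_psi fu_psi * lambda_b_psi *
    exp(-(lambda_b_psi + lambda_p) * t), its content decays physically at
    lambda_p, and it empties instantaneously every voiding interval.  The
    TIAC is the time integral of the content, accumulated cycle by cycle on
    a fine grid until the remaining inflow is negligible.
    """
    fu = np.asarray(fu, dtype=float)
    lam_b = np.asarray(lambda_bio, dtype=float)
    tv = voiding_interval_h
    u = np.linspace(0.0, tv, steps_per_cycle + 1)
    total = 0.0
    t0 = 0.0
    for _ in range(max_cycles):
        # content during one cycle: b(u) = e^{-lam_p u} * int_0^u r(t0+s) e^{+lam_p s} ds
        inflow = np.zeros_like(u)
        for f, lb in zip(fu, lam_b):
            inflow += f * lb * np.exp(-(lb + lambda_p) * (t0 + u))
        growth = cumulative_trapezoid(inflow * np.exp(lambda_p * u), u, initial=0.0)
        content = np.exp(-lambda_p * u) * growth
        cycle_integral = float(trapezoid(content, u))
        total += cycle_integral
        t0 += tv
        if cycle_integral <= residual * max(total, 1e-300):
            break
    return total
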