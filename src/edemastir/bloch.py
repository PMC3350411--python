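"""Numerical reference simulator for inversion-recovery longitudinal dynamics.

Integrates the longitudinal Bloch equation ``dMz/dt = (M0 - Mz)/T1``
piecewise through the pulse events of a single-readout inversion-recovery
cycle (instantaneous inversion, free recovery to the readout, saturation by
the excitation pulse, free recovery for the rest of the repetition), cycling
until a steady state is reached.

This is a validation utility: it shares no code with the closed forms in
:mod:`edemastir.mr_signal` and exists so the analytic steady-state
expression can be checked against direct numerical integration.
"""

from __future__ import annotations

import math

from scipy.integrate import solve_ivp

__all__ = ["simulate_mz_at_readout"]


def _relax(mz0: float, duration: float, t1: float, rtol: float, atol: float) -> float:
    """Integrate free T1 recovery numerically over ``duration`` ms."""
    if duration == 0:
        return mz0
    sol = solve_ivp(
        lambda t, m: (1.0 - m) / t1,
        (0.0, duration),
        [mz0],
        method="DOP853",
        rtol=rtol,
        atol=atol,
    )
    return float(sol.y[0, -1])


def simulate_mz_at_readout(
    t1: float,
    ti: float,
    tr: float = math.inf,
    rtol: float = 1e-12,
    atol: float = 1e-13,
    max_cycles: int = 60,
    steady_tol: float = 1e-13,
) -> float:
    """Steady-state Mz at the excitation pulse, by piecewise integration.

    The cycle is: 180 degree inversion (Mz -> -Mz), recovery over TI,
    readout (recorded, then Mz set to 0 by the 90 degree pulse), recovery
    over TR - TI.  With ``tr=inf`` the magnetization fully relaxes between
    repetitions and a single cycle suffices.
    """
    if not (t1 > 0 and ti > 0 and tr > ti):
        raise ValueError("require t1 > 0, ti > 0, tr > ti")
    if math.isinf(tr):
        return _relax(-1.0, ti, t1, rtol, atol)
    mz = 1.0
    previous = None
    for _ in range(max_cycles):
        at_readout = _relax(-mz, ti, t1, rtol, atol)
        mz = _relax(0.0, tr - ti, t1, rtol, atol)
        if previous is not None and abs(at_readout - previous) < steady_tol:
            return at_readout
        previous = at_readout
    return previous
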