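"""Resting-drive calibration: search the Poisson drive rate that yields a
target population firing rate."""

from __future__ import annotations

__all__ = ["calibrate_resting_input", "CalibrationError"]


class CalibrationError(RuntimeError):
    """The search failed to bracket or converge; carries diagnostics."""

    def __init__(self, msg, history):
        super().__init__(f"{msg}; history (rate -> Hz): {history}")
        self.history = history


def calibrate_resting_input(measure_rate, target_rate_hz: float,
                            tol_hz: float = 0.5, max_iter: int = 20,
                            initial_rate: float = 1000.0,
                            bracket_factor: float = 4.0) -> float:
    """Drive rate whose measured response is within ``tol_hz`` of target.

    ``measure_rate(drive_hz) -> Hz`` runs the embedding module for a probe
    window and reports the population mean rate; it must be (stochastically)
    monotone in the drive.  The search brackets the target by geometric
    expansion, then bisects; a strictly positive tolerance is required
    because the response is a stochastic simulation.
    """
    if target_rate_hz <= 0:
        raise ValueError("target rate must be > 0")
    if tol_hz <= 0:
        raise CalibrationError(
            "tolerance must be strictly positive for a stochastic probe", []
        )
    history = []

    def f(rate):
        r = measure_rate(rate)
        history.append((rate, r))
        return r

    lo = hi = initial_rate
    r = f(initial_rate)
    if abs(r - target_rate_hz) <= tol_hz:
        return initial_rate
    it = 0
    if r < target_rate_hz:
        while r < target_rate_hz and it < max_iter:
            lo, hi = hi, hi * bracket_factor
            r = f(hi)
            it += 1
        if r < target_rate_hz:
            raise CalibrationError("failed to bracket the target from below", history)
    else:
        while r > target_rate_hz and it < max_iter:
            hi, lo = lo, lo / bracket_factor
            r = f(lo)
            it += 1
        if r > target_rate_hz:
            raise CalibrationError("failed to bracket the target from above", history)
    while it < max_iter:
        mid = 0.5 * (lo + hi)
        r = f(mid)
        it += 1
        if abs(r - target_rate_hz) <= tol_hz:
            return mid
        if r < target_rate_hz:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"no convergence within {max_iter} probes (target {target_rate_hz} "
        f"+- {tol_hz} Hz)", history,
    )
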