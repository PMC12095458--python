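"""One-tissue compartment model for pulmonary blood flow.

The tissue concentration obeys

    dC_T/dt = K1 * C_B(t - j) - k2 * C_T(t),

where C_B is the pulmonary-blood (right ventricle) input, K1 (mL/min/cm^3)
is the delivery rate — the pulmonary blood flow estimate — k2 (/min) the
washout rate, and j an integer transit delay in seconds.  The measured PET
signal mixes blood and tissue with air (assumed zero activity):

    C_PET(t) = V_B * C_B(t - j) + (1 - V_A - V_B) * C_T(t),

with air and blood volume fractions V_A, V_B in (0, 1).

Two forward evaluators are provided.  ``forward_discrete`` is the fitting
recursion on the 1 s grid,

    C_T(i) = K1 * C_B(i - j - 1) + (1 - k2) * C_T(i - 1),    C_T(0) = 0,

an explicit Euler step with per-second rate constants (note the input is
read one sample before the current one; the fitted delay absorbs the
offset).  ``forward_analytic`` evaluates the exact convolution solution
C_T = K1 * C_B(t - j) (x) exp(-k2 t) by fine-grid quadrature and serves as
an independent oracle for the recursion.  Rates are per-second throughout;
conversion to /min (x60) happens only at the reporting boundary.  No decay
constant appears: the data are assumed decay-corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, lfilter

from .tac import TimeActivityCurve

__all__ = [
    "KineticParams",
    "DELAY_GRID",
    "SECONDS_PER_MINUTE",
    "shift_input",
    "forward_discrete",
    "forward_analytic",
    "pet_signal",
]

SECONDS_PER_MINUTE = 60.0
#: Candidate transit delays (seconds) searched during fitting.
DELAY_GRID: tuple[int, ...] = tuple(range(16))


@dataclass(frozen=True)
class KineticParams:
    """Model parameters with per-second internal rate units.

    k1_per_s, k2_per_s
        Rate constants in /s; reported units (mL/min/cm^3 and /min) are
        obtained with the ``*_per_min`` properties (x60).
    va, vb
        Air and blood volume fractions, each in [0, 1).
    delay_s
        Integer transit delay j in seconds, in {0, ..., 15}.
    """

    k1_per_s: float
    k2_per_s: float
    va: float = 0.0
    vb: float = 0.0
    delay_s: int = 0

    def __post_init__(self) -> None:
        if self.k1_per_s < 0 or self.k2_per_s < 0:
            raise ValueError("rate constants must be non-negative")
        if not (0 <= self.va < 1 and 0 <= self.vb < 1):
            raise ValueError("volume fractions must lie in [0, 1)")
        if self.delay_s not in DELAY_GRID:
            raise ValueError(f"delay must be an integer in {DELAY_GRID[0]}..{DELAY_GRID[-1]}")

    @property
    def k1_per_min(self) -> float:
        """K1 in mL/min/cm^3 (reported unit)."""
        return self.k1_per_s * SECONDS_PER_MINUTE

    @property
    def k2_per_min(self) -> float:
        """k2 in /min (reported unit)."""
        return self.k2_per_s * SECONDS_PER_MINUTE

    @property
    def partition_coefficient(self) -> float:
        """Water partition coefficient K1/k2 (unitless; NaN if k2 = 0)."""
        if self.k2_per_s == 0:
            return float("nan")
        return self.k1_per_s / self.k2_per_s

    @property
    def tissue_weight(self) -> float:
        """1 - V_A - V_B, the tissue fraction of the PET signal."""
        return 1.0 - self.va - self.vb

    @property
    def effective_flux(self) -> float:
        """(1 - V_A - V_B) * K1 in /s: the only combination of V_A and K1
        the PET signal identifies when air activity is zero."""
        return self.tissue_weight * self.k1_per_s


def _validate_delay(j: int) -> int:
    if not (isinstance(j, (int, np.integer)) and DELAY_GRID[0] <= j <= DELAY_GRID[-1]):
        raise ValueError(f"delay must be an integer in 0..15, got {j!r}")
    return int(j)


def shift_input(cb: TimeActivityCurve, j: int) -> TimeActivityCurve:
    """Shift a uniform-1s input right by j seconds, zero-padding the left.

    The input before injection is zero, so C_B(t - j) for t < j is zero.
    Length is preserved.
    """
    j = _validate_delay(j)
    if cb.kind != "uniform-1s":
        raise ValueError("shift_input requires a uniform-1s curve")
    if j == 0:
        return cb.with_values(cb.values.copy())
    values = np.concatenate([np.zeros(j), cb.values[:-j]])
    return cb.with_values(values)


def _shift_samples(values: np.ndarray, n: int) -> np.ndarray:
    if n == 0:
        return values
    return np.concatenate([np.zeros(n), values[:-n]])


def forward_discrete(
    params: KineticParams, cb_values: np.ndarray, dt: float = 1.0
) -> np.ndarray:
    """Tissue series C_T from the fitting recursion.

    ``cb_values`` samples the input on a uniform grid of step ``dt``
    starting at t = 0.  At the default dt = 1 s this is exactly

        C_T(i) = K1 * C_B(i - j - 1) + (1 - k2) * C_T(i - 1),

    with C_T(0) = 0 and C_B indices below zero treated as zero.  For
    dt < 1 the generalised Euler step K1*dt and (1 - k2*dt) is used and the
    input is read one grid step plus j seconds earlier; dt must then divide
    the delay.  k2*dt >= 1 makes the recursion factor non-positive; this is
    permitted (the optimizer may pass through) but flagged with a warning.
    """
    cb_values = np.asarray(cb_values, dtype=float)
    j = _validate_delay(params.delay_s)
    if dt <= 0 or dt > 1.0:
        raise ValueError("dt must lie in (0, 1] seconds")
    steps = j / dt
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(f"dt={dt} must divide the delay {j} s")
    lag = int(round(steps)) + 1  # the recursion reads the input one step back
    if params.k2_per_s * dt >= 1.0:
        warnings.warn(
            f"k2*dt = {params.k2_per_s * dt:.3g} >= 1: the recursion factor "
            "1 - k2*dt is non-positive and the Euler step is unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    x = _shift_samples(cb_values, lag)
    a = 1.0 - params.k2_per_s * dt
    ct = lfilter([params.k1_per_s * dt], [1.0, -a], x)
    return ct


def forward_analytic(
    params: KineticParams,
    cb_times: np.ndarray,
    cb_values: np.ndarray,
    out_times: np.ndarray | None = None,
    dt: float = 0.05,
) -> np.ndarray:
    """Tissue series C_T from the exact convolution solution.

    The input is linearly interpolated onto a fine grid of step ``dt``
    (anchored at zero before its first sample), shifted continuously by the
    delay, and convolved with K1 * exp(-k2 t) by trapezoidal quadrature.
    Returns C_T at ``out_times`` (default: ``cb_times``).  Independent of
    the discrete recursion; used as its oracle (keep dt <= 0.1 s for
    oracle-grade accuracy).
    """
    if dt <= 0 or dt > 1.0:
        raise ValueError("quadrature step must lie in (0, 1] seconds")
    cb_times = np.asarray(cb_times, dtype=float)
    cb_values = np.asarray(cb_values, dtype=float)
    if out_times is None:
        out_times = cb_times
    out_times = np.asarray(out_times, dtype=float)
    t_max = float(max(cb_times[-1], out_times.max()))
    n = int(np.ceil(t_max / dt)) + 1
    fine_t = np.arange(n) * dt
    # shifted input: C_B(t - j), zero before the shifted support
    tp, vp = cb_times, cb_values
    if tp[0] > 0:
        tp = np.concatenate([[0.0], tp])
        vp = np.concatenate([[0.0], vp])
    cb_fine = np.interp(fine_t - params.delay_s, tp, vp, left=0.0)
    if params.k1_per_s == 0.0:
        ct_fine = np.zeros_like(fine_t)
    else:
        kernel = np.exp(-params.k2_per_s * fine_t)
        conv = fftconvolve(cb_fine, kernel)[:n]
        # trapezoid end-point correction of the Riemann sum
        ct_fine = params.k1_per_s * dt * (
            conv - 0.5 * (cb_fine[0] * kernel + cb_fine * kernel[0])
        )
    return np.interp(out_times, fine_t, ct_fine)


def pet_signal(
    ct: np.ndarray, cb_shifted: np.ndarray, va: float, vb: float
) -> np.ndarray:
    """Mix tissue and blood into the measured PET signal.

    C_PET = V_B * C_B(t - j) + (1 - V_A - V_B) * C_T(t); the air term
    carries zero activity.
    """
    ct = np.asarray(ct, dtype=float)
    cb_shifted = np.asarray(cb_shifted, dtype=float)
    if ct.shape != cb_shifted.shape:
        raise ValueError(
            f"length mismatch: C_T {ct.shape} vs shifted input {cb_shifted.shape}"
        )
    if not (0 <= va < 1 and 0 <= vb < 1):
        raise ValueError("volume fractions must lie in [0, 1)")
    return vb * cb_shifted + (1.0 - va - vb) * ct
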