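"""Post-processing of invasive LV pressure recordings.

Implements the catheterization-lab analysis chain: smoothed differentiation,
cardiac-cycle segmentation from the dP/dt upstroke, fiducial detection
(end-diastole, peak systole, post-relaxation end-systole), selection of a
five-beat end-expiration run, per-cycle derived parameters averaged over the
run, and the LVEDP-based diastolic-dysfunction call (LVEDP > 15 mmHg).

Two derivative series are used deliberately.  Detection (segmentation,
fiducials, reported dP/dt extrema) runs on a moving-average-smoothed
derivative, which is what makes it robust to catheter noise.  The
contraction/relaxation integrals are evaluated on the *raw* centered-difference
derivative between the detected fiducials, so that by the fundamental theorem
of calculus each integral telescopes to the pressure difference between its
bounds — the property the downstream tables rely on (contraction integral
= P_peak - P_ED, relaxation integral magnitude = P_peak - P_ES).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FiducialError, ParameterError, SegmentationError, SelectionError
from .waveform import PressureWaveform

__all__ = [
    "Fiducials",
    "HemodynamicParams",
    "compute_dpdt",
    "segment_cycles",
    "detect_fiducials",
    "select_end_expiration_cycles",
    "compute_hemodynamic_params",
    "classify_diastolic_dysfunction",
    "DEFAULT_SMOOTH_WINDOW",
]

DEFAULT_SMOOTH_WINDOW = 21  # samples; 21 ms at the default 1 kHz

# Onset = smoothed dP/dt crossing above this fraction of its global maximum.
_ONSET_FRACTION = 0.2
# End-diastole = last pre-upstroke sample with smoothed dP/dt below this
# fraction of the cycle's maximum dP/dt.
_ED_FRACTION = 0.1
# Refractory period as a fraction of the beat-to-beat interval.
_REFRACTORY_FRACTION = 0.3


@dataclass(frozen=True)
class Fiducials:
    """Landmark sample indices (and pressures) for one cardiac cycle.

    ``end_diastole_index`` may precede the cycle's onset boundary: end-diastole
    is found by scanning backwards from the upstroke onset into the tail of the
    filling phase.
    """

    end_diastole_index: int
    peak_systole_index: int
    end_systole_index: int
    end_diastole_pressure: float
    peak_systole_pressure: float
    end_systole_pressure: float

    def __post_init__(self) -> None:
        if not (self.end_diastole_index < self.peak_systole_index < self.end_systole_index):
            raise FiducialError(
                "fiducials out of order: ED %d, peak %d, ES %d"
                % (self.end_diastole_index, self.peak_systole_index, self.end_systole_index)
            )
        if self.peak_systole_pressure < max(
            self.end_diastole_pressure, self.end_systole_pressure
        ):
            raise FiducialError("peak-systolic pressure below another fiducial pressure")


@dataclass(frozen=True)
class HemodynamicParams:
    """Derived invasive parameters, averaged over the selected beats."""

    lvedp: float                    # mmHg
    lv_end_systolic_pressure: float  # mmHg
    max_dpdt: float                 # mmHg/s
    min_dpdt: float                 # mmHg/s
    contraction_integral: float     # mmHg
    relaxation_integral: float      # mmHg, reported as magnitude
    diastolic_integral: float       # mmHg*s
    n_cycles_used: int

    def as_dict(self) -> dict[str, float]:
        return {
            "lvedp": self.lvedp,
            "lvesp": self.lv_end_systolic_pressure,
            "max_dpdt": self.max_dpdt,
            "min_dpdt": self.min_dpdt,
            "contraction_integral": self.contraction_integral,
            "relaxation_integral": self.relaxation_integral,
            "diastolic_integral": self.diastolic_integral,
            "diastolic_dysfunction": classify_diastolic_dysfunction(self.lvedp),
        }


def compute_dpdt(waveform: PressureWaveform, smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """dP/dt in mmHg/s: zero-phase moving-average smoothing then centered differences.

    ``smooth_window`` must be odd so the moving average is symmetric (zero
    phase shift).  ``smooth_window=1`` disables smoothing and returns the raw
    centered-difference derivative (one-sided at the endpoints).  Output length
    equals input length.
    """
    n = len(waveform.pressure)
    if smooth_window < 1 or smooth_window % 2 == 0 or smooth_window >= n:
        raise ParameterError(
            f"smooth_window must be odd, >=1 and < series length {n}, got {smooth_window}"
        )
    p = waveform.pressure.astype(float)
    if smooth_window > 1:
        from scipy.ndimage import uniform_filter1d

        p = uniform_filter1d(p, size=smooth_window, mode="nearest")
    return np.gradient(p, waveform.dt)


def _dominant_period(waveform: PressureWaveform) -> float:
    """Beat period estimate from the dominant spectral line in 0.5-4 Hz."""
    p = waveform.pressure - np.mean(waveform.pressure)
    spectrum = np.abs(np.fft.rfft(p))
    freqs = np.fft.rfftfreq(len(p), waveform.dt)
    band = (freqs >= 0.5) & (freqs <= 4.0)
    if not np.any(band) or np.all(spectrum[band] == 0):
        raise SegmentationError("no dominant cardiac frequency in 0.5-4 Hz band")
    f0 = freqs[band][np.argmax(spectrum[band])]
    return 1.0 / f0


def _apply_refractory(crossings: np.ndarray, refractory_samples: int) -> list[int]:
    onsets: list[int] = []
    for idx in crossings:
        if not onsets or idx - onsets[-1] >= refractory_samples:
            onsets.append(int(idx))
    return onsets


def segment_cycles(
    waveform: PressureWaveform, smooth_window: int = DEFAULT_SMOOTH_WINDOW
) -> list[tuple[int, int]]:
    """Segment the recording into cardiac cycles at dP/dt upstroke onsets.

    Onsets are threshold crossings of the smoothed dP/dt above 20% of its
    global maximum, de-bounced with a refractory period of 30% of the
    beat-to-beat interval (initialized from the dominant spectral period, then
    refined from the median inter-onset interval).  Returns contiguous,
    non-overlapping ``[onset_i, onset_{i+1})`` index pairs; a trailing segment
    at least 70% of the median cycle long is kept as a final cycle.
    """
    if waveform.duration < 1.0:
        raise SegmentationError("waveform must be at least 1 s long")
    dpdt = compute_dpdt(waveform, smooth_window)
    peak = float(np.max(dpdt))
    if peak <= 0:
        raise SegmentationError("no positive dP/dt: signal has no upstrokes")
    threshold = _ONSET_FRACTION * peak
    above = dpdt > threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if len(crossings) < 2:
        raise SegmentationError(f"fewer than 2 upstroke onsets detected ({len(crossings)})")

    period = _dominant_period(waveform)
    refractory = int(round(_REFRACTORY_FRACTION * period * waveform.sampling_rate))
    onsets = _apply_refractory(crossings, max(refractory, 1))
    if len(onsets) >= 3:
        median_rr = float(np.median(np.diff(onsets)))
        refractory = int(round(_REFRACTORY_FRACTION * median_rr))
        onsets = _apply_refractory(crossings, max(refractory, 1))
    if len(onsets) < 2:
        raise SegmentationError("fewer than 2 upstroke onsets after refractory filtering")

    pairs = list(zip(onsets[:-1], onsets[1:]))
    median_len = float(np.median(np.diff(onsets)))
    tail = len(waveform.pressure) - onsets[-1]
    if tail >= 0.7 * median_len:
        pairs.append((onsets[-1], len(waveform.pressure)))
    return pairs


def detect_fiducials(
    waveform: PressureWaveform,
    cycle: tuple[int, int],
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    _dpdt: np.ndarray | None = None,
) -> Fiducials:
    """Locate end-diastole, peak systole and end-systole for one cycle.

    Peak systole is the pressure maximum in the cycle; end-systole is the
    pressure minimum between the peak and the cycle end (the post-relaxation
    nadir); end-diastole is the last sample before the upstroke onset at which
    the smoothed dP/dt falls below 10% of the cycle's maximum dP/dt.
    """
    a, b = cycle
    n = len(waveform.pressure)
    if not (0 <= a < b <= n):
        raise ParameterError(f"cycle ({a}, {b}) outside waveform bounds [0, {n})")
    p = waveform.pressure
    dpdt = compute_dpdt(waveform, smooth_window) if _dpdt is None else _dpdt

    peak = a + int(np.argmax(p[a:b]))
    if peak >= b - 1:
        raise FiducialError("no post-peak nadir: cycle is monotone rising into its end")
    es = peak + 1 + int(np.argmin(p[peak + 1 : b]))

    cyc_max = float(np.max(dpdt[a:b]))
    if cyc_max <= 0:
        raise FiducialError("cycle has no positive dP/dt")
    ed_threshold = _ED_FRACTION * cyc_max
    lookback = max(a - (b - a), 0)
    ed = -1
    for j in range(a, lookback - 1, -1):
        if dpdt[j] < ed_threshold:
            ed = j
            break
    if ed < 0 or ed >= peak:
        raise FiducialError("no end-diastole found before the upstroke")

    return Fiducials(
        end_diastole_index=ed,
        peak_systole_index=peak,
        end_systole_index=es,
        end_diastole_pressure=float(p[ed]),
        peak_systole_pressure=float(p[peak]),
        end_systole_pressure=float(p[es]),
    )


def select_end_expiration_cycles(
    waveform: PressureWaveform,
    cycles: list[tuple[int, int]],
    k: int = 5,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> list[int]:
    """Pick the run of ``k`` consecutive cycles at the respiratory trough.

    The run minimizing the mean end-diastolic (baseline) pressure is selected;
    ties break to the earliest run.  With no respiratory modulation all runs
    tie, so the first ``k`` cycles are returned.
    """
    if k < 1:
        raise ParameterError("k must be at least 1")
    if len(cycles) < k:
        raise SelectionError(f"need at least {k} cycles, found {len(cycles)}")
    dpdt = compute_dpdt(waveform, smooth_window)
    baselines = np.full(len(cycles), np.nan)
    for i, c in enumerate(cycles):
        try:
            baselines[i] = detect_fiducials(
                waveform, c, smooth_window, _dpdt=dpdt
            ).end_diastole_pressure
        except FiducialError:
            # e.g. a first cycle that starts mid-upstroke with no filling tail
            continue
    run_means = np.convolve(baselines, np.ones(k) / k, mode="valid")
    if np.all(np.isnan(run_means)):
        raise SelectionError(f"no run of {k} consecutive cycles with valid fiducials")
    # rounding makes exact ties (no respiration) resolve to the earliest run
    start = int(np.nanargmin(np.round(run_means, 9)))
    return list(range(start, start + k))


def compute_hemodynamic_params(
    waveform: PressureWaveform,
    k: int = 5,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> HemodynamicParams:
    """Derived invasive parameters averaged over a ``k``-beat end-expiration run.

    Per selected cycle: LVEDP and end-systolic pressure are read from the raw
    trace at the detected fiducials; dP/dt extrema are taken from the smoothed
    derivative over the cycle; the contraction and relaxation integrals are
    trapezoidal integrals of the raw derivative between fiducials (relaxation
    reported as magnitude); the diastolic integral is the trapezoidal
    pressure-time area from end-systole to the next cycle's end-diastole (or to
    the cycle end for the final cycle).  Parameters are then averaged
    (unweighted) over the ``k`` beats.
    """
    cycles = segment_cycles(waveform, smooth_window)
    selected = select_end_expiration_cycles(waveform, cycles, k, smooth_window)
    dpdt_smooth = compute_dpdt(waveform, smooth_window)
    dpdt_raw = compute_dpdt(waveform, 1)
    dt = waveform.dt
    p = waveform.pressure

    fiducials = {
        i: detect_fiducials(waveform, cycles[i], smooth_window, _dpdt=dpdt_smooth)
        for i in set(selected) | {i + 1 for i in selected if i + 1 < len(cycles)}
    }

    rows = []
    for i in selected:
        a, b = cycles[i]
        f = fiducials[i]
        ed, peak, es = f.end_diastole_index, f.peak_systole_index, f.end_systole_index
        contraction = float(np.trapezoid(dpdt_raw[ed : peak + 1], dx=dt))
        relaxation = abs(float(np.trapezoid(dpdt_raw[peak : es + 1], dx=dt)))
        next_ed = fiducials[i + 1].end_diastole_index if i + 1 in fiducials else b - 1
        if next_ed <= es:
            next_ed = b - 1
        diastolic = float(np.trapezoid(p[es : next_ed + 1], dx=dt))
        rows.append(
            (
                f.end_diastole_pressure,
                f.end_systole_pressure,
                float(np.max(dpdt_smooth[a:b])),
                float(np.min(dpdt_smooth[a:b])),
                contraction,
                relaxation,
                diastolic,
            )
        )

    means = np.mean(np.array(rows), axis=0)
    return HemodynamicParams(
        lvedp=float(means[0]),
        lv_end_systolic_pressure=float(means[1]),
        max_dpdt=float(means[2]),
        min_dpdt=float(means[3]),
        contraction_integral=float(means[4]),
        relaxation_integral=float(means[5]),
        diastolic_integral=float(means[6]),
        n_cycles_used=k,
    )


def classify_diastolic_dysfunction(lvedp: float) -> bool:
    """Diastolic dysfunction: invasively measured LVEDP strictly above 15 mmHg."""
    if not np.isfinite(lvedp):
        raise ParameterError(f"lvedp must be finite, got {lvedp}")
    return bool(lvedp > 15.0)
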