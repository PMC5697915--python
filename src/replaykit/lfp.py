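"""Local-field-potential analysis: band power, ripples, theta/delta state,
coherence.

The LFP (1.2 kHz) is band-pass filtered with a zero-phase FIR filter, an
analytic signal is formed with the Hilbert transform, and instantaneous power
is its squared complex modulus.  Sharp-wave ripples are detected as periods
where ripple-band (150-250 Hz) power exceeds the mean by 2.5 SD, with
boundaries extended to the mean-crossings, events closer than 40 ms merged,
and a 40-500 ms duration filter applied.  The log theta/delta power ratio
indexes the ongoing oscillatory state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sig
from scipy.fft import next_fast_len

THETA_BAND = (6.0, 12.0)
DELTA_BAND = (2.0, 4.0)
RIPPLE_BAND = (150.0, 250.0)
POWER_FLOOR = 1e-12


@dataclass
class BandPower:
    band_name: str
    band_hz: tuple
    fs_hz: float
    power: np.ndarray          # instantaneous power, squared analytic modulus


@dataclass
class RippleEvent:
    start: float
    end: float
    peak_power: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def _fir_bandpass(lo, hi, fs):
    # transition width narrow relative to both the band edge and the band
    # width, so narrow low-frequency bands (delta 2-4 Hz) keep a flat
    # passband; Hamming-window stop-band attenuation ~53 dB
    trans = max(min(lo / 2.0, (hi - lo) / 3.0), 0.5)
    numtaps = int(min(max(3.3 * fs / trans, 255), 16383)) | 1
    return sig.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)


def band_power(lfp_values, fs_hz: float, band: tuple, band_name: str = "",
               downsample_hz: float = None) -> BandPower:
    """Zero-phase band-pass filter, Hilbert transform, squared modulus.

    A pure in-band sinusoid of amplitude A yields constant power A^2 (away
    from the filter edges).  Optionally down-sampled (by striding) to match
    the 50 Hz position sampling.
    """
    lo, hi = band
    if hi >= fs_hz / 2:
        raise ValueError("band extends beyond Nyquist")
    x = np.asarray(lfp_values, dtype=float)
    taps = _fir_bandpass(lo, hi, fs_hz)
    # a symmetric FIR applied once with centered output is zero-phase
    filtered = sig.fftconvolve(x, taps, mode="same")
    nfft = next_fast_len(filtered.size)       # pad so the FFT-based transform stays fast
    analytic = sig.hilbert(filtered, N=nfft)[: filtered.size]
    power = np.abs(analytic) ** 2
    fs_out = fs_hz
    if downsample_hz:
        step = max(1, int(round(fs_hz / downsample_hz)))
        power = power[::step]
        fs_out = fs_hz / step
    return BandPower(band_name=band_name or f"{lo:g}-{hi:g}Hz", band_hz=band,
                     fs_hz=fs_out, power=power)


def theta_delta_ratio(lfp_values, fs_hz: float, floor: float = POWER_FLOOR) -> np.ndarray:
    """log(theta power / delta power) per sample; powers floored to avoid -inf."""
    theta = band_power(lfp_values, fs_hz, THETA_BAND, "theta").power
    delta = band_power(lfp_values, fs_hz, DELTA_BAND, "delta").power
    return np.log(np.maximum(theta, floor) / np.maximum(delta, floor))


def event_mean(series: np.ndarray, fs_hz: float, start: float, end: float, t0: float = 0.0):
    """Mean of a sampled series over [start, end] seconds."""
    i0 = max(0, int(np.floor((start - t0) * fs_hz)))
    i1 = min(series.size, int(np.ceil((end - t0) * fs_hz)) + 1)
    if i1 <= i0:
        return float("nan")
    return float(series[i0:i1].mean())


def detect_ripples(power: np.ndarray, fs_hz: float, threshold_sd: float = 2.5,
                   min_duration_s: float = 0.04, max_duration_s: float = 0.5,
                   merge_gap_s: float = 0.04, t0: float = 0.0) -> list:
    """Ripple events from an instantaneous ripple-band power series.

    Threshold mean + 2.5 SD, boundaries at the mean-crossings, gaps under
    40 ms merged, then the [40, 500] ms duration filter.
    """
    power = np.asarray(power, dtype=float)
    mean, sd = float(power.mean()), float(power.std())
    above = power > mean + threshold_sd * sd
    if not above.any():
        return []
    below = power <= mean
    d = np.diff(above.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        ends = ends + [power.size]
    intervals = []
    for s, e in zip(starts, ends):
        left = np.nonzero(below[: s + 1])[0]
        a = int(left[-1]) + 1 if left.size else 0
        right = np.nonzero(below[e:])[0]
        b = int(e + right[0]) if right.size else power.size
        if intervals and a <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], b))
        else:
            intervals.append((a, b))
    # merge events separated by less than the gap
    merged = []
    gap = merge_gap_s * fs_hz
    for a, b in intervals:
        if merged and a - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    out = []
    for a, b in merged:
        dur = (b - a) / fs_hz
        if min_duration_s <= dur <= max_duration_s:
            out.append(RippleEvent(start=t0 + a / fs_hz, end=t0 + b / fs_hz,
                                   peak_power=float(power[a:b].max())))
    return out


def theta_state_filter(event_ratios, running_ratio_mean: float, running_ratio_sd: float):
    """Control filter: keep events whose log(theta/delta) is at least 1 SD
    below the mean ratio measured during movement."""
    ratios = np.asarray(event_ratios, dtype=float)
    return ratios < running_ratio_mean - running_ratio_sd


def coherence_spectrum(lfp_a, lfp_b, fs_hz: float, windows: list = None,
                       max_freq_hz: float = 200.0, nperseg: int = 1024):
    """Magnitude-squared coherence up to 200 Hz, Welch-averaged.

    ``windows`` is an optional list of (start, end) seconds restricting the
    analysis to one behavioral condition; segments are concatenated.
    """
    a = np.asarray(lfp_a, dtype=float)
    b = np.asarray(lfp_b, dtype=float)
    if a.size != b.size:
        raise ValueError("signals must be aligned and equal length")
    if windows is not None:
        keep = np.zeros(a.size, dtype=bool)
        for w0, w1 in windows:
            keep[int(w0 * fs_hz): int(w1 * fs_hz)] = True
        a, b = a[keep], b[keep]
    if a.size < 2 * nperseg:
        raise ValueError("too few samples for the requested segment length")
    f, coh = sig.coherence(a, b, fs=fs_hz, nperseg=nperseg)
    sel = f <= max_freq_hz
    return f[sel], coh[sel]


def freq_correlation_matrix(lfp_a, fs_hz: float, lfp_b=None, nperseg: int = 512,
                            max_freq_hz: float = 200.0):
    """Frequency x frequency correlation of spectrogram power time series.

    With one signal this is the self-coherence matrix (diagonal 1); with two,
    rows index frequencies of the first signal and columns of the second.
    Constant power rows yield NaN (reported missing).
    """
    a = np.asarray(lfp_a, dtype=float)
    fa, _, Sa = sig.spectrogram(a, fs=fs_hz, nperseg=nperseg)
    sel = fa <= max_freq_hz
    Sa = Sa[sel]
    if lfp_b is None:
        Sb = Sa
    else:
        fb, _, Sb = sig.spectrogram(np.asarray(lfp_b, dtype=float), fs=fs_hz,
                                    nperseg=nperseg)
        Sb = Sb[fb <= max_freq_hz]
    na = Sa.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        full = np.corrcoef(np.vstack([Sa, Sb]))
    return fa[sel], full[:na, na:]
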