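"""Mean-vector-length phase-amplitude coupling with time-lag surrogate normalization.

The estimator quantifies how strongly the amplitude of a fast oscillation
(gamma, 30-40 Hz) depends on the phase of a slow one (theta/alpha, 4-12 Hz)
in a single regional time series:

1. band-pass both bands with a zero-phase (forward-backward) 4th-order
   Butterworth filter; by default the amplitude band is passed together
   with its two modulation-sideband windows (see
   :func:`modulation_sideband_bands`), without which a narrow amplitude
   band cannot carry modulation at the phase frequency at all;
2. take the Hilbert analytic signal; its angle in the low band is the
   instantaneous phase ``phi_L(t)``, its modulus in the high band the
   instantaneous amplitude ``A_H(t)``;
3. form the complex composite ``Z(t) = A_H(t) * exp(i * phi_L(t))`` and
   average it over the (edge-trimmed) record.  The mean vector ``M_raw`` is
   long when gamma amplitude concentrates at one low-frequency phase and
   short when amplitude and phase are independent;
4. calibrate against the no-coupling null by circularly time-lagging the
   amplitude series: surrogate lags destroy the phase/amplitude alignment
   while preserving both marginal distributions exactly.  The coupling
   strength is the z-score ``M_norm = (|M_raw| - mu) / sigma`` against the
   surrogate lengths, and the preferred coupling phase ``Phi_norm`` is the
   angle of ``M_raw`` in degrees.

``M_norm`` is a signed z-score: values below zero (observed mean vector
shorter than the typical surrogate) are meaningful and are never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt, sosfreqz

__all__ = [
    "PacParameterError",
    "DegenerateSurrogateError",
    "RegionalTimeSeries",
    "BandPair",
    "PacCell",
    "bandpass",
    "phase_series",
    "amplitude_series",
    "multiband_amplitude_series",
    "modulation_sideband_bands",
    "modulation_amplitude_series",
    "composite_signal",
    "raw_mean_vector",
    "surrogate_mvls",
    "normalized_pac",
    "pac_cell_from_series",
]

FILTER_ORDER = 4
#: Default number of time-lag surrogates used to z-score the mean vector length.
DEFAULT_N_SURROGATES = 200
#: Default minimum surrogate lag and default edge trim, both in seconds.
DEFAULT_MIN_LAG = 1.0
DEFAULT_TRIM = 1.0
#: Fewer surrogates than this gives too noisy a null mean/s.d. to z-score against.
MIN_SURROGATES = 50


class PacParameterError(ValueError):
    """Invalid analysis parameter (band edges, lags, lengths...)."""


class DegenerateSurrogateError(RuntimeError):
    """Surrogate mean-vector lengths have (numerically) zero spread.

    Happens when the amplitude envelope is constant, e.g. for a pure
    unmodulated sinusoid: every circular lag then yields the same mean
    vector and the z-score is undefined.
    """


@dataclass(frozen=True)
class RegionalTimeSeries:
    """One subject's signal in one brain region.

    Parameters
    ----------
    samples
        Real-valued signal vector; must be finite throughout.
    fs
        Sampling rate in Hz.  Must exceed twice the highest analysis
        frequency (so > 80 Hz for a 30-40 Hz amplitude band).
    subject_id, group, region
        Free-text labels carried through the pipeline and used to derive
        per-cell surrogate seeds.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    group: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise PacParameterError("samples must be one-dimensional")
        if samples.size < 2:
            raise PacParameterError("samples must contain at least two values")
        if not np.all(np.isfinite(samples)):
            raise PacParameterError("samples contain NaN or Inf")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise PacParameterError(f"fs must be a positive number, got {self.fs!r}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class BandPair:
    """A (phase band, amplitude band) pair of half-open frequency intervals in Hz."""

    phase_band: tuple[float, float]
    amp_band: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("phase_band", self.phase_band), ("amp_band", self.amp_band)):
            if not (0 < lo < hi):
                raise PacParameterError(f"{name} must satisfy 0 < f_lo < f_hi, got ({lo}, {hi})")
        object.__setattr__(self, "phase_band", (float(self.phase_band[0]), float(self.phase_band[1])))
        object.__setattr__(self, "amp_band", (float(self.amp_band[0]), float(self.amp_band[1])))


@dataclass(frozen=True)
class PacCell:
    """Surrogate-normalized coupling result for one phase-band x amplitude-band pair."""

    m_raw: complex
    mu: float
    sigma: float
    m_norm: float
    phi_norm_deg: float
    n_surrogates: int

    def to_dict(self) -> dict:
        return {
            "m_raw_re": float(self.m_raw.real),
            "m_raw_im": float(self.m_raw.imag),
            "mu": self.mu,
            "sigma": self.sigma,
            "m_norm": self.m_norm,
            "phi_norm_deg": self.phi_norm_deg,
            "n_surrogates": self.n_surrogates,
        }


def _check_band(band: tuple[float, float], fs: float) -> tuple[float, float]:
    lo, hi = float(band[0]), float(band[1])
    if not (0 < lo < hi < fs / 2):
        raise PacParameterError(
            f"band ({lo}, {hi}) Hz must lie strictly inside (0, {fs / 2}) Hz at fs={fs}"
        )
    return lo, hi


def bandpass(x: RegionalTimeSeries, band: tuple[float, float], order: int = FILTER_ORDER) -> np.ndarray:
    """Zero-phase Butterworth band-pass of ``x.samples``.

    The filter runs forward and backward (``sosfiltfilt``) so the output has
    no phase lag; this keeps the low-band phase and high-band amplitude
    series aligned in time, which the composite signal requires.
    """
    lo, hi = _check_band(band, x.fs)
    sos = butter(order, (lo, hi), btype="bandpass", fs=x.fs, output="sos")
    return sosfiltfilt(sos, x.samples)


def phase_series(x: RegionalTimeSeries, phase_band: tuple[float, float]) -> np.ndarray:
    """Instantaneous phase phi_L(t) in (-pi, pi] of the band-passed signal."""
    return np.angle(hilbert(bandpass(x, phase_band)))


def amplitude_series(x: RegionalTimeSeries, amp_band: tuple[float, float]) -> np.ndarray:
    """Instantaneous amplitude A_H(t) >= 0 of the band-passed signal."""
    return np.abs(hilbert(bandpass(x, amp_band)))


@lru_cache(maxsize=2048)
def _band_gain(lo: float, hi: float, n: int, fs: float, order: int) -> np.ndarray:
    """Squared-magnitude Butterworth band-pass response on the length-n rFFT grid.

    The squared magnitude is the response of the forward-backward
    (zero-phase) filter.  Cached because grids re-use the same few dozen
    bands across cells and subjects; treat the returned array as read-only.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sos = butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    _, h = sosfreqz(sos, worN=freqs, fs=fs)
    return np.abs(h) ** 2


def _multiband_gain(
    bands: tuple[tuple[float, float], ...], n: int, fs: float, order: int
) -> np.ndarray:
    """Summed zero-phase response over disjoint pass bands (one linear comb filter)."""
    last_hi = 0.0
    for band in bands:
        lo, hi = _check_band(band, fs)
        if lo < last_hi:
            raise PacParameterError(f"amplitude pass bands overlap or are unsorted: {bands}")
        last_hi = hi
    gain = np.zeros(n // 2 + 1)
    for lo, hi in bands:
        gain += _band_gain(float(lo), float(hi), int(n), float(fs), int(order))
    return gain


def multiband_amplitude_series(
    x: RegionalTimeSeries,
    bands: tuple[tuple[float, float], ...],
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Instantaneous amplitude of the signal restricted to a union of pass bands.

    Filtering happens in the frequency domain with the squared Butterworth
    magnitude response (exactly zero-phase, the magnitude a forward-backward
    Butterworth would apply); the analytic signal is formed in the same
    pass, so one FFT round-trip yields the envelope.  Wrap-around edge
    effects are confined to the trimmed margins downstream.
    """
    n = x.n_samples
    gain = _multiband_gain(tuple(bands), n, x.fs, order)
    half = np.fft.rfft(x.samples) * gain
    # analytic-signal spectrum: double positive frequencies, keep DC/Nyquist
    spectrum = np.zeros(n, dtype=np.complex128)
    spectrum[0] = half[0]
    if n % 2 == 0:
        spectrum[1 : n // 2] = 2.0 * half[1 : n // 2]
        spectrum[n // 2] = half[n // 2]
    else:
        spectrum[1 : (n + 1) // 2] = 2.0 * half[1:]
    return np.abs(np.fft.ifft(spectrum))


def modulation_sideband_bands(
    phase_band: tuple[float, float], amp_band: tuple[float, float]
) -> tuple[tuple[float, float], ...]:
    """The amplitude pass windows for carriers in ``amp_band`` modulated at ``phase_band``.

    Amplitude modulation of a carrier at f_a by phases at f_p puts sidebands
    at f_a +/- f_p.  To measure the modulated amplitude of carriers inside
    the nominal bin — and only those — the filter passes the bin itself plus
    its two sideband images shifted down/up by the phase band.  A single
    wide band would also pass carriers belonging to neighbouring bins, which
    blurs the comodulogram along the amplitude axis; a bare 1 Hz band would
    strip the sidebands and see no modulation at all.
    """
    p_lo, p_hi = phase_band
    a_lo, a_hi = amp_band
    if p_lo <= (a_hi - a_lo):
        raise PacParameterError(
            f"phase band {phase_band} overlaps the amplitude bin width; "
            "sideband windows would collide with the carrier bin"
        )
    return ((a_lo - p_hi, a_hi - p_lo), (a_lo, a_hi), (a_lo + p_lo, a_hi + p_hi))


def modulation_amplitude_series(
    x: RegionalTimeSeries,
    phase_band: tuple[float, float],
    amp_band: tuple[float, float],
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Amplitude series of ``amp_band`` carriers including their modulation sidebands."""
    return multiband_amplitude_series(
        x, modulation_sideband_bands(phase_band, amp_band), order=order
    )


def composite_signal(amp: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Z(t) = A_H(t) * exp(i * phi_L(t)), element-wise."""
    amp = np.asarray(amp, dtype=np.float64)
    phase = np.asarray(phase, dtype=np.float64)
    if amp.shape != phase.shape:
        raise PacParameterError(
            f"amplitude and phase series differ in shape: {amp.shape} vs {phase.shape}"
        )
    return amp * np.exp(1j * phase)


def raw_mean_vector(z: np.ndarray) -> complex:
    """Arithmetic mean of the composite signal (the raw mean vector M_raw)."""
    z = np.asarray(z)
    if z.size == 0:
        raise PacParameterError("composite signal is empty")
    return complex(z.mean())


def _phase_kernel(z_unit: np.ndarray) -> np.ndarray:
    """FFT kernel for all-lag circular means against unit phasors ``z_unit``.

    With ``w[k] = fft(z_unit)[(-k) % n]``, ``ifft(fft(a) * w)[tau] / n``
    equals ``mean(a[(t + tau) % n] * z_unit[t])`` for every lag tau.
    """
    fz = np.fft.fft(z_unit)
    return np.roll(fz[::-1], 1)


def _all_lag_mean_vectors(amp: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular-lag mean vectors c[tau] = mean(A_H(t+tau) e^{i phi_L(t)}) for all tau."""
    n = amp.size
    return np.fft.ifft(np.fft.fft(amp) * kernel) / n


def _draw_lags(
    n: int, fs: float, n_surrogates: int, min_lag: float, rng: np.random.Generator
) -> np.ndarray:
    lag_lo = int(round(min_lag * fs))
    lag_hi = n - lag_lo
    if lag_lo < 1 or lag_lo >= lag_hi:
        raise PacParameterError(
            f"signal of {n} samples is too short for min_lag={min_lag} s at fs={fs} Hz"
        )
    return rng.integers(lag_lo, lag_hi, size=n_surrogates, endpoint=True)


def surrogate_mvls(
    amp: np.ndarray,
    phase: np.ndarray,
    fs: float,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    min_lag: float = DEFAULT_MIN_LAG,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mean-vector lengths of time-lag surrogates.

    Each surrogate circularly shifts the amplitude series by an
    independently drawn lag ``tau ~ Uniform[min_lag, T - min_lag]`` (in
    samples) while keeping the phase series fixed, then measures
    ``|mean(A_H(t + tau) e^{i phi_L(t)})|``.  The circular shift preserves
    the marginal distribution of A_H exactly, which is what the
    normalization requires.
    """
    amp = np.asarray(amp, dtype=np.float64)
    phase = np.asarray(phase, dtype=np.float64)
    if amp.shape != phase.shape or amp.ndim != 1:
        raise PacParameterError("amplitude and phase series must be 1-D and equal length")
    if n_surrogates < MIN_SURROGATES:
        raise PacParameterError(f"n_surrogates must be >= {MIN_SURROGATES}, got {n_surrogates}")
    if rng is None:
        rng = np.random.default_rng()
    lags = _draw_lags(amp.size, fs, n_surrogates, min_lag, rng)
    c = _all_lag_mean_vectors(amp, _phase_kernel(np.exp(1j * phase)))
    return np.abs(c[lags])


def pac_cell_from_series(
    amp: np.ndarray,
    phase: np.ndarray,
    fs: float,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    min_lag: float = DEFAULT_MIN_LAG,
    rng: np.random.Generator | None = None,
) -> PacCell:
    """Normalized PAC from already-trimmed amplitude and phase series.

    This is the computational core shared by :func:`normalized_pac` and the
    grid assembly: one FFT cross-correlation yields the mean vector at every
    circular lag; lag 0 is the observed ``M_raw`` and the drawn lags are the
    surrogates.
    """
    amp = np.asarray(amp, dtype=np.float64)
    phase = np.asarray(phase, dtype=np.float64)
    if amp.shape != phase.shape or amp.ndim != 1 or amp.size == 0:
        raise PacParameterError("amplitude and phase series must be 1-D, nonempty, equal length")
    if n_surrogates < MIN_SURROGATES:
        raise PacParameterError(f"n_surrogates must be >= {MIN_SURROGATES}, got {n_surrogates}")
    if rng is None:
        rng = np.random.default_rng()
    lags = _draw_lags(amp.size, fs, n_surrogates, min_lag, rng)
    c = _all_lag_mean_vectors(amp, _phase_kernel(np.exp(1j * phase)))
    m_raw = complex(c[0])
    lengths = np.abs(c[lags])
    mu = float(lengths.mean())
    sigma = float(lengths.std(ddof=1))
    if not np.isfinite(sigma) or sigma <= 1e-9 * max(mu, np.finfo(float).tiny):
        raise DegenerateSurrogateError(
            "surrogate mean-vector lengths have zero spread "
            "(constant amplitude envelope?); M_norm is undefined"
        )
    m_norm = (abs(m_raw) - mu) / sigma
    phi_norm_deg = wrap_degrees(np.degrees(np.angle(m_raw)))
    return PacCell(
        m_raw=m_raw,
        mu=mu,
        sigma=sigma,
        m_norm=float(m_norm),
        phi_norm_deg=phi_norm_deg,
        n_surrogates=int(n_surrogates),
    )


def wrap_degrees(angle_deg: float) -> float:
    """Map an angle in degrees onto [0, 360); guards the 360.0 rounding edge."""
    wrapped = float(angle_deg) % 360.0
    return 0.0 if wrapped >= 360.0 else wrapped


def trim_slice(n: int, fs: float, trim: float) -> slice:
    """Interior slice after removing ``trim`` seconds of filter/Hilbert edge transient per end."""
    k = int(round(trim * fs))
    if k < 0:
        raise PacParameterError("trim must be non-negative")
    if 2 * k >= n:
        raise PacParameterError(f"trim={trim} s removes the whole {n}-sample record at fs={fs}")
    return slice(k, n - k if k else None)


def normalized_pac(
    x: RegionalTimeSeries,
    pair: BandPair,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    min_lag: float = DEFAULT_MIN_LAG,
    rng: np.random.Generator | None = None,
    trim: float = DEFAULT_TRIM,
    amp_filter: str = "sidebands",
) -> PacCell:
    """Surrogate-normalized PAC of one time series for one band pair.

    ``amp_filter="sidebands"`` (default) extracts the amplitude through the
    carrier bin plus its modulation-sideband windows (see
    :func:`modulation_sideband_bands`); ``"plain"`` uses the bare band-pass
    envelope of ``pair.amp_band``, which only sees modulation slower than
    half the band width.

    Filtering and the Hilbert transform run on the full record; ``trim``
    seconds are then discarded from each end of both series before the
    composite signal is formed, so edge transients never enter the mean
    vector or the surrogates.
    """
    phase = phase_series(x, pair.phase_band)
    if amp_filter == "sidebands":
        amp = modulation_amplitude_series(x, pair.phase_band, pair.amp_band)
    elif amp_filter == "plain":
        amp = amplitude_series(x, pair.amp_band)
    else:
        raise PacParameterError("amp_filter must be 'sidebands' or 'plain'")
    sl = trim_slice(x.n_samples, x.fs, trim)
    return pac_cell_from_series(
        amp[sl], phase[sl], x.fs, n_surrogates=n_surrogates, min_lag=min_lag, rng=rng
    )
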