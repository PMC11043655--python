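"""Synthetic regional time series and two-group cohorts with known coupling.

The generator produces the kind of signal the PAC estimator presumes: a
low-frequency (4-12 Hz) oscillation embedded in 1/f-like background noise,
plus a gamma (30-40 Hz) oscillation whose amplitude is modulated by the
low-frequency phase with controllable depth ``kappa`` and preferred phase.

Signal model (per subject and region)::

    theta(t) = 2*pi*f_phase*t + phi0 + W(t)               # phi0 ~ U(-pi, pi]
    x(t) = lf_amplitude * cos(theta(t))
         + hf_amplitude * (1 + kappa*cos(theta(t) - preferred_phase)) / (1 + kappa)
                        * sin(2*pi*f_amp*t + psi0)
         + pink_noise(noise_exponent, noise_sd)

The cosine low-frequency carrier makes the Hilbert instantaneous phase equal
``theta(t)`` exactly, so the gamma envelope peaks where the measured phase
equals ``preferred_phase`` and downstream angle recovery has no built-in
offset.  ``kappa = 0`` gives an envelope that is independent of the
low-frequency phase; the ``1/(1+kappa)`` normalization keeps the envelope
peak at ``hf_amplitude`` for every coupling depth.

``W(t)`` is a Brownian phase walk with diffusion coefficient
``phase_jitter`` (rad per sqrt-second).  It gives the low-frequency
oscillation a finite coherence time (Lorentzian linewidth
``phase_jitter**2 / (2*pi)`` Hz, ~0.6 Hz at the default 2.0), as real
neural rhythms have.  This matters beyond realism: a perfectly periodic
modulation is invariant under circular time lags, so lag surrogates could
never destroy its coupling and the surrogate-normalized index would be
blind to it.  Phase diffusion is what makes amplitude and phase decorrelate
at lags of a second or more.

Determinism: every random quantity (phase offsets, gamma carrier phase,
noise) comes from a generator derived from the cohort seed plus subject and
region labels, so the same spec always reproduces bit-identical signals in
any order and across processes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeding import rng_for
from .pac import PacParameterError, RegionalTimeSeries

__all__ = [
    "CouplingSpec",
    "SyntheticCohortSpec",
    "generate_pink_noise",
    "generate_coupled_signal",
    "generate_cohort",
    "two_group_spec",
]


@dataclass(frozen=True)
class CouplingSpec:
    """Parameters of one group's signal in one region.

    f_phase / f_amp are the low- and high-frequency carriers in Hz; kappa is
    the dimensionless modulation depth (0 = no coupling); preferred_phase is
    the low-frequency phase (radians) at which the gamma envelope peaks;
    noise_sd and noise_exponent set the standard deviation and spectral
    slope of the 1/f^alpha background; phase_jitter (rad/sqrt(s)) sets the
    low-frequency phase diffusion, i.e. how quickly the rhythm loses
    coherence.
    """

    f_phase: float = 6.5
    f_amp: float = 34.5
    kappa: float = 0.5
    preferred_phase: float = np.pi / 2
    lf_amplitude: float = 1.0
    hf_amplitude: float = 0.5
    noise_sd: float = 1.0
    noise_exponent: float = 1.0
    phase_jitter: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.f_phase < self.f_amp):
            raise PacParameterError(
                f"need 0 < f_phase < f_amp, got f_phase={self.f_phase}, f_amp={self.f_amp}"
            )
        if self.kappa < 0:
            raise PacParameterError("kappa must be >= 0")
        if self.lf_amplitude <= 0:
            raise PacParameterError("lf_amplitude must be > 0")
        if self.hf_amplitude < 0 or self.noise_sd < 0 or self.noise_exponent < 0:
            raise PacParameterError("amplitudes, noise_sd and noise_exponent must be >= 0")
        if self.phase_jitter < 0:
            raise PacParameterError("phase_jitter must be >= 0")
        if not (-np.pi < self.preferred_phase <= np.pi):
            # wrap rather than reject: angles are circular
            wrapped = float(np.angle(np.exp(1j * self.preferred_phase)))
            object.__setattr__(self, "preferred_phase", wrapped)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Two-group cohort: per-region coupling parameters for each group label.

    ``coupling`` maps region -> {group label -> CouplingSpec}; both group
    labels must be present for every region.  Defaults mirror the target
    acquisition (600 Hz sampling, 60 s epochs).
    """

    n_group_a: int
    n_group_b: int
    coupling: dict[str, dict[str, CouplingSpec]]
    label_a: str = "A"
    label_b: str = "B"
    fs: float = 600.0
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise PacParameterError("each group needs at least 2 subjects")
        if not self.coupling:
            raise PacParameterError("at least one region is required")
        if self.label_a == self.label_b:
            raise PacParameterError("group labels must differ")
        for region, by_group in self.coupling.items():
            for label in (self.label_a, self.label_b):
                if label not in by_group:
                    raise PacParameterError(
                        f"region {region!r} has no CouplingSpec for group {label!r}"
                    )

    @property
    def regions(self) -> list[str]:
        return list(self.coupling)


def generate_pink_noise(
    n: int, exponent: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian 1/f^alpha noise by spectral shaping of white noise.

    The rFFT of white Gaussian noise is multiplied by f^(-alpha/2) (DC
    zeroed), inverted, and rescaled so the sample standard deviation equals
    ``sd`` exactly.  alpha=0 reduces to white noise; sd=0 returns zeros.
    """
    if n < 2:
        raise PacParameterError("n must be >= 2")
    if sd < 0 or exponent < 0:
        raise PacParameterError("sd and exponent must be >= 0")
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if exponent == 0:
        shaped = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n)
        scale = np.zeros_like(f)
        scale[1:] = f[1:] ** (-exponent / 2.0)
        shaped = np.fft.irfft(spec * scale, n)
    s = shaped.std()
    if s == 0:  # pragma: no cover - white noise of n>=2 is never exactly constant
        return np.zeros(n)
    return shaped * (sd / s)


def _validate_signal_params(spec: CouplingSpec, fs: float, duration: float) -> int:
    if fs <= 2 * spec.f_amp:
        raise PacParameterError(f"fs={fs} must exceed 2*f_amp={2 * spec.f_amp}")
    if duration < 10.0 / spec.f_phase:
        raise PacParameterError(
            f"duration={duration} s is shorter than 10 low-frequency cycles "
            f"({10.0 / spec.f_phase:.2f} s at {spec.f_phase} Hz)"
        )
    n = int(np.floor(fs * duration))
    if n < 2:
        raise PacParameterError("fs * duration must give at least 2 samples")
    return n


def generate_coupled_signal(
    spec: CouplingSpec,
    fs: float,
    duration: float,
    rng: np.random.Generator,
    subject_id: str = "",
    group: str = "",
    region: str = "",
    phi0: float | None = None,
) -> RegionalTimeSeries:
    """One phase-amplitude-coupled signal of ``floor(fs * duration)`` samples.

    ``phi0`` (the low-frequency phase offset) is drawn uniformly from
    (-pi, pi] when not given; the gamma carrier phase is always drawn from
    ``rng``.
    """
    n = _validate_signal_params(spec, fs, duration)
    if phi0 is None:
        phi0 = float(rng.uniform(-np.pi, np.pi))
    psi0 = float(rng.uniform(-np.pi, np.pi))
    t = np.arange(n) / fs
    theta = 2 * np.pi * spec.f_phase * t + phi0
    if spec.phase_jitter > 0:
        steps = rng.normal(0.0, spec.phase_jitter / np.sqrt(fs), n)
        theta = theta + np.cumsum(steps)
    envelope = (1.0 + spec.kappa * np.cos(theta - spec.preferred_phase)) / (1.0 + spec.kappa)
    x = (
        spec.lf_amplitude * np.cos(theta)
        + spec.hf_amplitude * envelope * np.sin(2 * np.pi * spec.f_amp * t + psi0)
        + generate_pink_noise(n, spec.noise_exponent, spec.noise_sd, rng)
    )
    return RegionalTimeSeries(
        samples=x, fs=fs, subject_id=subject_id, group=group, region=region
    )


def _subject_ids(spec: SyntheticCohortSpec) -> list[tuple[str, str]]:
    ids = [(f"{spec.label_a}{i + 1:03d}", spec.label_a) for i in range(spec.n_group_a)]
    ids += [(f"{spec.label_b}{i + 1:03d}", spec.label_b) for i in range(spec.n_group_b)]
    return ids


def generate_cohort(spec: SyntheticCohortSpec) -> list[RegionalTimeSeries]:
    """All subject x region signals of a two-group cohort.

    Each subject gets one random low-frequency phase offset shared across
    regions (so group-level phase-angle statistics are exercised
    nontrivially), and independent noise and gamma carrier phase per region.
    """
    cohort: list[RegionalTimeSeries] = []
    for subject_id, label in _subject_ids(spec):
        phi0 = float(rng_for(spec.seed, subject_id, "phi0").uniform(-np.pi, np.pi))
        for region in spec.regions:
            cspec = spec.coupling[region][label]
            rng = rng_for(spec.seed, subject_id, region)
            cohort.append(
                generate_coupled_signal(
                    cspec,
                    spec.fs,
                    spec.duration,
                    rng,
                    subject_id=subject_id,
                    group=label,
                    region=region,
                    phi0=phi0,
                )
            )
    return cohort


def two_group_spec(
    n_group_a: int,
    n_group_b: int,
    regions: list[str],
    spec_a: CouplingSpec,
    spec_b: CouplingSpec,
    contrast_region: str | None = None,
    **kwargs,
) -> SyntheticCohortSpec:
    """Convenience builder: identical coupling everywhere except ``contrast_region``.

    In ``contrast_region`` group A follows ``spec_a`` and group B ``spec_b``;
    elsewhere both groups follow ``spec_a``.  With ``contrast_region=None``
    the groups differ in every region.
    """
    label_a = kwargs.pop("label_a", "A")
    label_b = kwargs.pop("label_b", "B")
    coupling = {}
    for region in regions:
        if contrast_region is None or region == contrast_region:
            coupling[region] = {label_a: spec_a, label_b: spec_b}
        else:
            coupling[region] = {label_a: spec_a, label_b: spec_a}
    return SyntheticCohortSpec(
        n_group_a=n_group_a,
        n_group_b=n_group_b,
        coupling=coupling,
        label_a=label_a,
        label_b=label_b,
        **kwargs,
    )
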