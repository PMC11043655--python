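# Methods

This note documents the models, parameters and numerical choices behind
`pacgrid`, and what its synthetic validation does and does not establish.

## The coupling estimator

Coupling between a low-frequency phase band and a high-frequency amplitude
band is quantified by the surrogate-normalized mean vector length.  Both
series come from zero-phase 4th-order Butterworth filtering followed by the
Hilbert transform; zero-phase filtering is required so the phase and
amplitude series stay aligned in time.  The composite signal
Z(t) = A_H(t)·e^{iΦ_L(t)} is averaged over the record; the asymmetry of its
distribution about the origin — the raw mean vector M_raw — measures how
strongly amplitude concentrates at one phase.

**Surrogate normalization.**  |M_raw| has no absolute scale (it grows with
signal amplitude and shrinks with record length), so it is z-scored against
a null in which the amplitude series is circularly time-lagged against the
phase series: M_norm = (|M_raw| − μ)/σ with μ, σ the mean and standard
deviation of the surrogate mean-vector *lengths*.  Lags are drawn uniformly
from [min_lag, T − min_lag] (default min_lag = 1 s) and applied as circular
shifts, which preserve the marginal distribution of A_H exactly.  The
default surrogate count is 200; at least 50 are required, since σ estimated
from fewer draws is too noisy to z-score against.  All surrogate lengths at
every lag are obtained from a single FFT circular cross-correlation, which
is exact (a unit test pins it to an explicit per-sample loop at 1e-10).

M_norm is signed and never clipped: a value below zero means the observed
mean vector is shorter than the typical surrogate.  The preferred phase
Φ_norm = arg M_raw is reported in degrees in [0, 360).

**Amplitude filter structure.**  Amplitude modulation at rate f_p places
sidebands at f_a ± f_p.  Two naive filter choices fail for a comodulogram
with 1 Hz amplitude bins and 4–12 Hz modulators: a bare 1 Hz band strips
the sidebands, leaving a constant envelope and no measurable coupling at
any modulation rate above 0.5 Hz; a single band widened by ±f_p passes the
sidebands but also the carriers of every neighbouring bin, so all bins
report nearly the same z-score and the grid loses amplitude resolution (in
piloting, argmax localization collapsed to 10–80% under this scheme).  The
default therefore passes, per cell, the nominal 1 Hz carrier bin plus its
two modulation-sideband windows — [a_lo − p_hi, a_hi − p_lo], [a_lo, a_hi],
[a_lo + p_lo, a_hi + p_hi] — as one linear zero-phase filter.  Only
carriers inside the nominal bin then contribute measurable modulation, so
the grid detects (z ≈ 10 at a seeded cell) *and* localizes (argmax at the
seeded cell in 20/20 pilot realizations).  The comb is implemented in the
frequency domain with the squared Butterworth magnitude response (the exact
magnitude of a forward-backward filter, exactly zero phase); a unit test
checks agreement with time-domain `sosfiltfilt` + Hilbert to better than 1%
RMS on trimmed interiors.  `amp_filter="plain"` with optional symmetric
`amp_band_expand` remains available for sensitivity studies.

**Edge handling.**  Filtering and the Hilbert transform run on the full
record; 1 s (configurable) is trimmed from each end of both series before
Z(t) is formed, removing filter and wrap-around transients (the narrowest
1 Hz band rings for about 1 s).

**Degenerate inputs.**  If the surrogate lengths have (numerically) zero
spread — e.g. a pure unmodulated sinusoid, whose envelope is constant —
the z-score is undefined and a `DegenerateSurrogateError` is raised naming
the offending grid cell; σ is tested against a relative floor of 1e−9·μ so
float jitter cannot masquerade as a valid null spread.

## The grid

The default comodulogram is 8 one-Hz phase bins over 4–12 Hz × 10 one-Hz
amplitude bins over 30–40 Hz (80 cells); bins are half-open [f, f+1).
Every cell draws its surrogate lags from a generator derived by SHA-256
from (grid seed, subject, region, phase bin, amplitude bin), so any cell is
reproducible in isolation, results are independent of evaluation order, and
cohort runs are reproducible across processes.

## Group comparison

Per region, cell-wise independent two-sample t-tests (equal variances,
df = nA + nB − 2, group A minus group B) are thresholded at two-tailed
p < 0.05; equal-sign supra-threshold cells are clustered under 4-neighbour
adjacency (±1 phase bin or ±1 amplitude bin; 8-connectivity available) and
each cluster's mass is its signed t-sum.  The null distribution is the
maximum |mass| over clusters per whole-subject label permutation (0 when a
permutation has no clusters), pooling both signs, which controls
family-wise error across directions; the default is 1024 permutations and
p_perm = (1 + #{null ≥ |mass|})/(1 + n_perm), never exactly zero.  Whole-
subject permutation preserves the within-subject correlation structure of
the 80 cells, which per-cell value shuffling would destroy.  Regions are
tested independently with no cross-region correction.  Subjects are sorted
by id within groups before any draw, so results are invariant to input
order.  In degenerate synthetic inputs a permuted split can give zero
pooled variance with zero mean difference; such 0/0 cells are set to t = 0
to keep the map finite.

Preferred-phase summaries: per subject, the cells of significant clusters
(p_perm < 0.05) contribute their unit-normalized complex M_raw; the angle
of the sum is the subject's mean phase.  Averaging complex values rather
than angles is what keeps the estimate correct across the 0°/360° wrap.
The group contrast on phase is a linear unpaired equal-variance t-test on
wrapped degrees — the reference behaviour — with group circular means
reported alongside.  The wraparound hazard of the linear test is real:
angle distributions straddling 0/360 can mislead it even when circular
means agree, which is why the circular means are always reported too.

## The synthetic generator

Each subject × region signal is

    x(t) = A_lf·cos θ(t)
         + A_hf·[1 + κ·cos(θ(t) − φ_pref)]/(1 + κ)·sin(2π f_a t + ψ0)
         + 1/f^α Gaussian noise,
    θ(t) = 2π f_p t + φ0 + W(t),

with φ0 uniform per subject (shared across regions so group phase
statistics are nontrivial), ψ0 uniform per region, and W(t) a Brownian
phase walk with diffusion `phase_jitter` (default 2.0 rad/√s, a ~0.6 Hz
Lorentzian linewidth).  The cosine low-frequency carrier makes the Hilbert
phase equal θ(t) exactly, so the envelope peaks where the *measured* phase
equals φ_pref and angle recovery has no built-in offset.  The phase walk is
essential, not cosmetic: a strictly periodic modulation is invariant under
circular time lags, so lag surrogates could never destroy its coupling and
the normalized index would be blind to it; finite phase coherence is also
what real neural rhythms have.  The 1/f^α background is synthesized by
spectral shaping of white noise (α default 1.0, typical of resting M/EEG)
and rescaled to the requested standard deviation exactly.

Standard study conditions: 600 Hz sampling and 60 s epochs (matching the
target acquisition), A_lf = 1, A_hf = 0.5, noise s.d. 1.0 ("low noise": the
1/f background leaves only ~10% of its s.d. near the theta band and far
less near gamma), coupling seeded at (6.5 Hz, 34.5 Hz) with φ_pref = 90°.
Scaled-down conditions used where many replicates are needed: 20 s records,
50 surrogates, 200 permutations.

**What the generator does not emulate:** broadband/bursty gamma,
asymmetric (non-sinusoidal) waveforms that produce spurious PAC, spatially
correlated noise across regions, artefacts, or epileptiform transients.
Passing synthetic validation therefore shows the pipeline recovers coupling
of the modelled form under realistic SNR; it does not certify robustness to
waveform-shape confounds, which the estimator (like all mean-vector-length
PAC) does not correct for.

## Validation summary (computed by tests and `scripts/acceptance.py`)

- Null calibration: over 200 uncoupled signals, M_norm has mean within
  ±0.35, s.d. in [0.6, 1.6] and P(M_norm > 1.645) in [0.01, 0.12].  The
  exceedance sits slightly above the nominal 5% because the surrogate null
  of |M_raw| is right-skewed and σ comes from 50 draws.
- Coupling recovery: κ = 1 at (6.5, 34.5) → grid argmax at the seeded cell
  in ≥ 18/20 realizations with M_norm > 3 (typically ≈ 13).
- Phase recovery: seeded 90° recovered within ±15° (circular mean of 20).
- Cluster machinery equals a brute-force BFS oracle exactly on 100 random
  t-maps.
- Permutation test: family-wise type-I error in [0.01, 0.10] at nominal 5%
  (measured ≈ 0.04 over large runs); a κ = 1 vs 0 difference with 15
  subjects per group is detected with a cluster overlapping the seeded
  block in ≥ 18/20 runs.
- Determinism: a full pipeline run is byte-identical under a fixed config.

## Known limitations

- The estimator inherits all caveats of mean-vector-length PAC: sensitivity
  to waveform shape, dependence of absolute M_norm on record length and
  surrogate count, and reduced interpretability when the phase band carries
  little oscillatory power.
- The linear phase-angle t-test is kept as the reference contrast for
  comparability; use the reported circular means to sanity-check it near
  the wrap.
- 1 Hz amplitude-bin resolution relies on the sideband-window filter; with
  `amp_filter="plain"` the grid is faithful to a literal per-bin band-pass
  reading but insensitive to modulation faster than half the bin width.
- No sensor-space processing: the pipeline starts at regional time series;
  beamforming, atlas mapping and artefact rejection are upstream concerns.
  A Welch PSD helper (`qc_psd`) supports eyeballing record quality only.
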