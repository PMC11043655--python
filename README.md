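# pacgrid

Resting-state gamma phase-amplitude coupling (PAC) grids with cluster-based
permutation group statistics.

Gamma-band activity (30–40 Hz) in the resting human brain is too weak for
conventional spectral power estimates, but its amplitude is modulated by the
phase of slower theta/alpha rhythms (4–12 Hz).  That cross-frequency
coupling is both a readout of local gamma activity and an index of neural
circuit excitability, which makes it interesting wherever local circuit
function is disturbed — for example in medial temporal regions vulnerable
to neurodegeneration.  `pacgrid` is for researchers who have per-subject,
per-region source-space time series (e.g. beamformed MEG mapped to an
atlas) and want a tested, reproducible pipeline from raw regional signals
to a region-level two-group comparison of coupling strength and preferred
coupling phase.

## The estimator

For one time series and one (phase band, amplitude band) pair:

- Φ_L(t): instantaneous phase of the zero-phase band-passed low-frequency
  signal (Hilbert transform);
- A_H(t): instantaneous amplitude of the high-frequency band.  The
  amplitude filter passes the nominal 1 Hz carrier bin *plus its two
  modulation-sideband windows* (the bin shifted down/up by the phase band),
  so 1 Hz amplitude bins remain sensitive to modulation and resolvable;
- composite signal Z(t) = A_H(t)·e^{iΦ_L(t)}, raw mean vector
  M_raw = ⟨Z(t)⟩.  |M_raw| is large when gamma amplitude concentrates at
  one low-frequency phase;
- surrogate normalization: circular time lags τ (drawn uniformly, ≥ 1 s)
  give null mean vectors ⟨A_H(t+τ)e^{iΦ_L(t)}⟩ whose lengths have mean μ
  and s.d. σ.  The coupling strength is the z-score

      M_norm = (|M_raw| − μ) / σ

  (signed — negative values are meaningful), and the preferred coupling
  phase is Φ_norm = arg M_raw in degrees.

A comodulogram ("PAC grid") evaluates this on 8 one-Hz phase bins
(4–12 Hz) × 10 one-Hz amplitude bins (30–40 Hz) = 80 cells per subject and
region.  Two groups of grids are compared per region with independent
t-tests per cell, clusters of adjacent supra-threshold cells (4-neighbour
adjacency, cluster α = 5%), and a max-cluster permutation null (1024
group-label permutations by default).  Preferred-phase summaries average
complex unit vectors over the significant cells per subject and compare
groups with an unpaired t-test.

A synthetic-cohort generator produces signals with known coupling depth
κ, preferred phase, 1/f background noise and finite low-frequency phase
coherence, so every stage has a ground-truth test surface.

## Worked example

```python
import numpy as np
from pacgrid import (BandPair, CouplingSpec, GridSpec, compute_grid,
                     generate_coupled_signal, normalized_pac)
from pacgrid._seeding import rng_for

# 60 s at 600 Hz: theta at 6.5 Hz modulating gamma at 34.5 Hz, kappa = 1,
# envelope peaking at the 90-degree theta phase, 1/f background noise
spec = CouplingSpec(f_phase=6.5, f_amp=34.5, kappa=1.0,
                    preferred_phase=np.pi / 2, hf_amplitude=0.5, noise_sd=1.0)
ts = generate_coupled_signal(spec, fs=600.0, duration=60.0,
                             rng=rng_for(42), subject_id="demo")

cell = normalized_pac(ts, BandPair(phase_band=(6, 7), amp_band=(34, 35)),
                      n_surrogates=200, rng=rng_for(42, "surrogates"))
print(f"M_norm = {cell.m_norm:.2f}, Phi_norm = {cell.phi_norm_deg:.1f} deg")

grid = compute_grid(ts, GridSpec(n_surrogates=200, seed=42))
print("argmax cell:", grid.argmax_cell())
```

prints

```
M_norm = 11.22, Phi_norm = 87.0 deg
argmax cell: (2, 4)
```

i.e. the coupling is 11.2 surrogate standard deviations above the
no-coupling null, the recovered preferred phase is within 3° of the seeded
90°, and the strongest cell of the 80-cell grid is phase bin [6, 7) Hz ×
amplitude bin [34, 35) Hz — exactly where the coupling was seeded.

## Command line

```bash
pacgrid simulate --config cohort.yaml --out cohort/      # synthetic cohort
pacgrid pac --input cohort/control001__r.csv \
            --phase-band 6 7 --amp-band 34 35 --seed 1   # one cell as JSON
pacgrid grid --input cohort/ --out grids.csv             # all 80-cell grids
pacgrid compare --grids grids.csv --group-a control --group-b patient \
                --n-perm 1024 --seed 1 --out report.json # cluster test
pacgrid run --config cohort.yaml                         # all of the above
pacgrid report --report out/report.json --out-dir figs/  # t-map / polar PNGs
```

`pacgrid run` writes `grids.csv`, `report.json` (t-maps, clusters with
permutation p-values, phase summaries) and `manifest.json` (config hash,
seeds, version); outputs are byte-identical across runs of the same
config.

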