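from __future__ import annotations

import numpy as np
import pytest

from pacgrid import CouplingSpec, GridSpec, generate_coupled_signal
from pacgrid._seeding import rng_for

FS = 600.0


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def make_coupled():
    """Factory for coupled test signals (20 s at 600 Hz unless overridden)."""

    def _make(
        kappa=1.0,
        noise_sd=1.0,
        preferred_phase=np.pi / 2,
        duration=20.0,
        fs=FS,
        seed=0,
        phase_jitter=2.0,
        **kwargs,
    ):
        spec = CouplingSpec(
            kappa=kappa,
            noise_sd=noise_sd,
            preferred_phase=preferred_phase,
            phase_jitter=phase_jitter,
            **kwargs,
        )
        return generate_coupled_signal(
            spec, fs, duration, rng_for("fixture", seed), subject_id=f"S{seed:03d}"
        )

    return _make


@pytest.fixture
def fast_grid_spec():
    """Reduced surrogate count for quick grid computations in unit tests."""
    return GridSpec(n_surrogates=50, seed=99)


def demo_config_yaml(tmp_path, n_per_group=5, seed=11, out_name="out"):
    """Write a small two-region demo pipeline config and return its path.

    Group A couples strongly in the seeded region, group B not at all;
    the second region is identical across groups.
    """
    coupled = """
        f_phase: 6.5
        f_amp: 34.5
        kappa: 1.0
        preferred_phase_deg: 90.0
        hf_amplitude: 0.5
        noise_sd: 1.0
"""
    uncoupled = coupled.replace("kappa: 1.0", "kappa: 0.0")
    text = f"""
cohort:
  n_group_a: {n_per_group}
  n_group_b: {n_per_group}
  label_a: control
  label_b: patient
  fs: 600.0
  duration: 20.0
  seed: {seed}
  regions:
    left_parahippocampal:
      control: {coupled}
      patient: {uncoupled}
    left_entorhinal:
      control: {coupled}
      patient: {coupled}
grid:
  n_surrogates: 50
  seed: {seed}
stats:
  n_perm: 200
  cluster_alpha: 0.05
  seed: {seed}
output:
  dir: {out_name}
"""
    path = tmp_path / "config.yaml"
    path.write_text(text)
    return path
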