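"""Shared fixtures: small synthetic datasets built at test time."""

import math

import numpy as np
import pytest

import callsig as cs


@pytest.fixture(scope="session")
def zero_variance_hierarchy():
    """Deterministic one-bat configuration (no hierarchical variance)."""
    return cs.HierarchyConfig(n_colonies=1, individuals_per_colony=1,
                              notes_per_individual=3, seed=7,
                              snr_db=math.inf)


@pytest.fixture(scope="session")
def desmodus_note(zero_variance_hierarchy):
    """One noiseless species-mean note plus its spectrogram and track."""
    spec = cs.sample_population(cs.DESMODUS, zero_variance_hierarchy)[0]
    wave = cs.synthesize_note(spec)
    spect = cs.compute_spectrogram(wave, 250_000)
    note = (0.0, spec.duration_ms / 1000.0)
    track = cs.track_fundamental(spect, note)
    return spec, wave, spect, track, note


def make_linear_sweep(f_start_khz=36.0, f_end_khz=18.0, duration_ms=10.0,
                      harmonic_offsets_db=(-math.inf,) * 3):
    """A pure linear FM sweep CallSpec (fundamental only by default)."""
    return cs.CallSpec(
        species="sweep", population="p", colony="c", individual="i",
        sex="F", session="s1", call_id="c1", note_index=1,
        duration_ms=duration_ms,
        f0_anchors_khz=((0.0, f_start_khz), (1.0, f_end_khz)),
        harmonic_offsets_db=harmonic_offsets_db)


@pytest.fixture(scope="session")
def linear_sweep_features():
    """Extracted measurements of a noiseless 36->18 kHz, 10 ms sweep."""
    spec = make_linear_sweep()
    wave = cs.synthesize_note(spec)
    spect = cs.compute_spectrogram(wave, 250_000)
    note = (0.0, 0.010)
    track = cs.track_fundamental(spect, note)
    return cs.extract_features(spect, track, note)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A written 2-colony Diaemus dataset with extracted features.

    Small (2 colonies x 2 bats x 10 calls) but exercises the full
    WAV -> annotation -> spectrogram -> measurement path once per
    session; double notes are frequent for this species.
    """
    out = tmp_path_factory.mktemp("dataset")
    profile = cs.DIAEMUS
    hierarchy = cs.HierarchyConfig(
        n_colonies=2, individuals_per_colony=2, notes_per_individual=10,
        seed=11, snr_db=30.0, **cs.realistic_sds(profile))
    specs = cs.sample_population(profile, hierarchy)
    annotations = cs.write_dataset(specs, out, seed=11)
    features = cs.extract_table(annotations, out)
    return specs, annotations, features


def one_way_scores(rng, n_groups=20, n_per_group=25, sb=1.0, sw=1.0):
    """Balanced one-way random-effects draws plus their group labels."""
    effects = rng.normal(0.0, sb, n_groups)
    y = np.repeat(effects, n_per_group) + rng.normal(
        0.0, sw, n_groups * n_per_group)
    groups = np.repeat(np.arange(n_groups), n_per_group)
    return y, groups
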