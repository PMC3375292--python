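"""Synthetic contact-call generator.

Produces datasets of downward frequency-modulated sweep notes with a
nested random-effects structure on the acoustic parameters: every
perturbable parameter of a note is the species mean plus a colony
effect, an individual effect, and a per-note effect, each Gaussian with
a configurable standard deviation.  Colony and individual effects are
drawn once per colony/individual and shared by all of their notes, which
is exactly the variance structure the downstream variance-component and
discriminant analyses assume.

Waveforms are rendered as harmonic stacks (fundamental plus up to three
harmonics) whose instantaneous fundamental frequency follows a monotone
interpolant through the per-note anchor frequencies, sampled at 250 kHz
and written as 16-bit PCM WAV plus a ground-truth annotation CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.io import wavfile

from .profiles import SpeciesProfile

DEFAULT_SAMPLING_RATE = 250_000
_MAX_RESAMPLE_ATTEMPTS = 100


@dataclass
class HierarchyConfig:
    """Nested population structure and per-level variation.

    ``notes_per_individual`` is the number of calls elicited per
    individual (each call contributes one first note; multi-note calls
    add further notes according to the species' note-count
    distribution).  The ``sd_*`` mappings give per-parameter standard
    deviations; keys are parameter names (``"duration_ms"``,
    ``"f0@0.5"``, ``"h1_db"``, ...) or the shorthands ``"f0"`` (all
    fundamental anchors) and ``"harmonics"`` (all harmonic offsets).
    """

    n_colonies: int = 2
    individuals_per_colony: int = 4
    notes_per_individual: int = 60
    sd_colony: dict[str, float] = field(default_factory=dict)
    sd_individual: dict[str, float] = field(default_factory=dict)
    sd_within: dict[str, float] = field(default_factory=dict)
    sd_session: dict[str, float] = field(default_factory=dict)
    n_sessions: int = 1
    snr_db: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_colonies, self.individuals_per_colony,
               self.notes_per_individual, self.n_sessions) < 1:
            raise ValueError("hierarchy sizes must be positive integers")
        for name in ("sd_colony", "sd_individual", "sd_within", "sd_session"):
            sds = getattr(self, name)
            if any(v < 0 for v in sds.values()):
                raise ValueError(f"{name} standard deviations must be >= 0")


def realistic_sds(profile: SpeciesProfile) -> dict[str, dict[str, float]]:
    """Default per-level standard deviations for a species profile.

    Scaled to the species means so that individual-level repeatability
    of single parameters lands near 0.2-0.35, matching the large
    within-individual variation these calls show relative to their
    between-individual signature variation.
    """
    f0_scale = float(np.mean(profile.anchor_freqs_khz))
    return {
        "sd_colony": {"duration_ms": 0.04 * profile.duration_ms,
                      "f0": 0.02 * f0_scale, "harmonics": 0.75},
        "sd_individual": {"duration_ms": 0.08 * profile.duration_ms,
                          "f0": 0.045 * f0_scale, "harmonics": 1.5},
        "sd_within": {"duration_ms": 0.10 * profile.duration_ms,
                      "f0": 0.06 * f0_scale, "harmonics": 2.0},
    }


@dataclass
class CallSpec:
    """Ground-truth parameters of one synthetic note."""

    species: str
    population: str
    colony: str
    individual: str
    sex: str
    session: str
    call_id: str
    note_index: int  # 1-based within the call
    duration_ms: float
    f0_anchors_khz: tuple[tuple[float, float], ...]
    harmonic_offsets_db: tuple[float, float, float]
    onset_time_s: float = 0.0
    snr_db: float = math.inf
    inter_note_interval_ms: float | None = None  # gap before this note

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        positions = [p for p, _ in self.f0_anchors_khz]
        if positions != sorted(positions) or positions[0] != 0.0 or positions[-1] != 1.0:
            raise ValueError("anchors must be ordered with positions covering 0 and 1")

    @property
    def labels(self) -> dict[str, object]:
        return {
            "species": self.species, "population": self.population,
            "colony": self.colony, "individual": self.individual,
            "sex": self.sex, "session": self.session,
            "call_id": self.call_id, "note_index": self.note_index,
        }

    def f0_interpolant(self, kind: str = "pchip") -> PchipInterpolator:
        """Monotone interpolant of the fundamental (kHz) vs relative position."""
        pos = np.array([p for p, _ in self.f0_anchors_khz])
        freq = np.array([f for _, f in self.f0_anchors_khz])
        if kind == "linear":
            # degenerate pchip: linear via numpy interp wrapped for API parity
            return lambda x: np.interp(x, pos, freq)  # type: ignore[return-value]
        return PchipInterpolator(pos, freq)


@dataclass
class AnnotatedRecording:
    """A rendered waveform with note annotations (one per CallSpec)."""

    waveform: np.ndarray
    sampling_rate_hz: int
    annotations: list[tuple[float, float, CallSpec]]

    def __post_init__(self) -> None:
        n = len(self.waveform)
        dur = n / self.sampling_rate_hz
        prev_end = -1.0
        for start, end, _ in self.annotations:
            if not (0.0 <= start < end <= dur + 1e-9):
                raise ValueError("annotation interval outside waveform")
            if start < prev_end - 1e-12:
                raise ValueError("annotations overlap")
            prev_end = end


# ---------------------------------------------------------------------------
# population sampling


def _param_names(profile: SpeciesProfile) -> list[str]:
    names = ["duration_ms"]
    names += [f"f0@{p:g}" for p in profile.anchor_positions]
    names += [f"h{k}_db" for k in (1, 2, 3)]
    return names


def _expand_sds(sds: dict[str, float], profile: SpeciesProfile) -> np.ndarray:
    names = _param_names(profile)
    out = np.zeros(len(names))
    for key, val in sds.items():
        if key == "f0":
            for i, n in enumerate(names):
                if n.startswith("f0@"):
                    out[i] = val
        elif key == "harmonics":
            for i, n in enumerate(names):
                if n.startswith("h"):
                    out[i] = val
        elif key in names:
            out[names.index(key)] = val
        else:
            raise KeyError(f"unknown perturbable parameter {key!r}; "
                           f"valid names: {names} plus 'f0'/'harmonics'")
    return out


def _mean_vector(profile: SpeciesProfile) -> np.ndarray:
    return np.array([profile.duration_ms, *profile.anchor_freqs_khz,
                     *profile.harmonic_offsets_db])


def _spec_from_vector(vec: np.ndarray, profile: SpeciesProfile,
                      nyquist_khz: float) -> tuple | None:
    """Unpack a parameter vector; None if the downward-sweep invariant fails."""
    duration = float(vec[0])
    n_anchor = len(profile.anchor_positions)
    freqs = vec[1:1 + n_anchor]
    offsets = tuple(float(v) for v in vec[1 + n_anchor:])
    if duration <= 0 or np.any(freqs <= 0) or np.any(freqs >= nyquist_khz):
        return None
    limit = [f for p, f in zip(profile.anchor_positions, freqs) if p <= 0.9 + 1e-9]
    if any(b >= a for a, b in zip(limit, limit[1:])):
        return None
    if freqs[-1] > limit[-1]:  # keep the tail non-increasing too
        return None
    anchors = tuple(zip(profile.anchor_positions, (float(f) for f in freqs)))
    return duration, anchors, offsets


def sample_population(
    profile: SpeciesProfile,
    hierarchy: HierarchyConfig,
    *,
    population: str = "captive",
    sampling_rate_hz: int = DEFAULT_SAMPLING_RATE,
    inter_call_gap_ms: float = 200.0,
) -> list[CallSpec]:
    """Draw a hierarchically structured set of notes for one species.

    Colony and individual effects are sampled once per level and reused
    for all of that level's notes; note effects are independent per
    note.  Later notes of a multi-note call share the call's first-note
    colony/individual effects (they belong to the same bat) but receive
    independent note effects.  Perturbations that would break the
    downward-sweep invariant are redrawn up to 100 times, after which a
    ``ValueError`` signals that the configured variance is too large for
    the profile.
    """
    rng = np.random.default_rng(hierarchy.seed)
    nyquist_khz = sampling_rate_hz / 2000.0
    names = _param_names(profile)
    mean = _mean_vector(profile)
    sd_c = _expand_sds(hierarchy.sd_colony, profile)
    sd_i = _expand_sds(hierarchy.sd_individual, profile)
    sd_w = _expand_sds(hierarchy.sd_within, profile)
    sd_s = _expand_sds(hierarchy.sd_session, profile)

    # anchors past the 90% position ride along with the last in-sweep
    # anchor: the profile's terminal shape is fixed and only the end
    # frequency shifts, so tiny tail gaps cannot be inverted by noise
    positions = profile.anchor_positions
    tail_idx = [1 + i for i, p in enumerate(positions) if p > 0.9 + 1e-9]
    ref_idx = 1 + max(i for i, p in enumerate(positions) if p <= 0.9 + 1e-9)

    def _couple_tail(vec: np.ndarray) -> np.ndarray:
        for t in tail_idx:
            vec[t] = mean[t] + (vec[ref_idx] - mean[ref_idx])
        return vec

    note_counts = sorted(profile.notes_per_call_dist)
    note_probs = [profile.notes_per_call_dist[k] for k in note_counts]

    specs: list[CallSpec] = []
    subject = 0
    for c in range(hierarchy.n_colonies):
        colony = f"{profile.name}_{population}_col{c + 1}"
        colony_eff = rng.normal(0.0, 1.0, len(names)) * sd_c
        for j in range(hierarchy.individuals_per_colony):
            indiv = f"{colony}_bat{j + 1}"
            sex = "F" if subject % 2 == 0 else "M"
            subject += 1
            indiv_eff = rng.normal(0.0, 1.0, len(names)) * sd_i
            session_effs = [rng.normal(0.0, 1.0, len(names)) * sd_s
                            for _ in range(hierarchy.n_sessions)]
            t_cursor = {s: 0.05 for s in range(hierarchy.n_sessions)}
            for call in range(hierarchy.notes_per_individual):
                sess = call % hierarchy.n_sessions
                session = f"s{sess + 1}"
                call_id = f"{indiv}_{session}_c{call + 1:04d}"
                n_notes = note_counts[
                    rng.choice(len(note_counts), p=note_probs)]
                base = mean + colony_eff + indiv_eff + session_effs[sess]
                onset = t_cursor[sess]
                for k in range(n_notes):
                    unpacked = None
                    for _ in range(_MAX_RESAMPLE_ATTEMPTS):
                        vec = _couple_tail(
                            base + rng.normal(0.0, 1.0, len(names)) * sd_w)
                        unpacked = _spec_from_vector(vec, profile, nyquist_khz)
                        if unpacked is not None:
                            break
                    if unpacked is None:
                        raise ValueError(
                            f"could not preserve the downward-sweep invariant "
                            f"after {_MAX_RESAMPLE_ATTEMPTS} attempts: "
                            f"configured variance too large for profile "
                            f"{profile.name!r}")
                    duration, anchors, offsets = unpacked
                    interval = None
                    if k > 0:
                        interval = float(max(
                            5.0, rng.normal(profile.inter_note_interval_ms, 1.0)))
                        onset += interval / 1000.0
                    specs.append(CallSpec(
                        species=profile.name, population=population,
                        colony=colony, individual=indiv, sex=sex,
                        session=session, call_id=call_id, note_index=k + 1,
                        duration_ms=duration, f0_anchors_khz=anchors,
                        harmonic_offsets_db=offsets, onset_time_s=onset,
                        snr_db=hierarchy.snr_db,
                        inter_note_interval_ms=interval))
                    onset += duration / 1000.0
                t_cursor[sess] = onset + inter_call_gap_ms / 1000.0
    return specs


# ---------------------------------------------------------------------------
# waveform synthesis


def synthesize_note(
    spec: CallSpec,
    sampling_rate_hz: int = DEFAULT_SAMPLING_RATE,
    *,
    n_harmonics: int = 3,
    envelope_fraction: float = 0.10,
    f0_interpolation: str = "pchip",
) -> np.ndarray:
    """Render one note as a float waveform (no noise, peak amplitude 1).

    The fundamental follows a monotone interpolant through the anchor
    frequencies; partial ``k'`` (1 = fundamental) is a sinusoid at
    ``k'`` times the instantaneous fundamental with amplitude set by the
    harmonic dB offsets, gated to zero wherever it would exceed 95% of
    Nyquist.  A raised-cosine ramp of ``envelope_fraction`` of the
    duration shapes each end of the note.
    """
    fs = sampling_rate_hz
    nyq_hz = fs / 2.0
    n = int(round(spec.duration_ms / 1000.0 * fs))
    if n < 2:
        raise ValueError("note too short to synthesize at this sampling rate")
    rel = np.arange(n) / n  # relative position in the note
    f0 = spec.f0_interpolant(f0_interpolation)
    f0_hz = np.asarray(f0(rel), dtype=float) * 1000.0
    if f0_hz.max() >= nyq_hz:
        raise ValueError(
            f"fundamental reaches {f0_hz.max():.0f} Hz, at or above the "
            f"Nyquist frequency {nyq_hz:.0f} Hz (partial 1 aliases)")
    # phase of the fundamental: cumulative integral of f0
    phase = 2.0 * np.pi * np.cumsum(f0_hz) / fs

    amps = [1.0]
    for off in spec.harmonic_offsets_db[:n_harmonics]:
        amps.append(10.0 ** (off / 20.0) if math.isfinite(off) else 0.0)

    wave = np.zeros(n)
    for k, a_k in enumerate(amps):
        if a_k == 0.0:
            continue
        partial_hz = (k + 1) * f0_hz
        gate = (partial_hz < 0.95 * nyq_hz).astype(float)
        if not gate.any():
            continue
        # short taper at the gate boundary to avoid clicks
        taper = max(1, int(0.0002 * fs))
        if gate.min() < 1.0:
            kernel = np.ones(taper) / taper
            gate = np.convolve(gate, kernel, mode="same")
        wave += a_k * gate * np.sin((k + 1) * phase)

    ramp = max(1, int(envelope_fraction * n))
    env = np.ones(n)
    ridx = np.arange(ramp)
    env[:ramp] = 0.5 * (1.0 - np.cos(np.pi * ridx / ramp))
    env[n - ramp:] = 0.5 * (1.0 - np.cos(np.pi * (n - 1 - np.arange(n - ramp, n)) / ramp))
    wave *= env
    peak = np.abs(wave).max()
    if peak > 0:
        wave /= peak
    return wave


def render_recording(
    specs: list[CallSpec],
    sampling_rate_hz: int = DEFAULT_SAMPLING_RATE,
    *,
    rng: np.random.Generator | None = None,
    pad_s: float = 0.05,
    **synth_kwargs,
) -> AnnotatedRecording:
    """Place notes at their onset times in one waveform, add noise.

    Noise is white Gaussian, scaled so that the ratio of the peak
    short-time note power to the noise power equals the smallest
    ``snr_db`` among the notes (infinite SNR leaves the recording
    noiseless).
    """
    if not specs:
        raise ValueError("render_recording needs at least one CallSpec")
    fs = sampling_rate_hz
    specs = sorted(specs, key=lambda s: s.onset_time_s)
    end_s = max(s.onset_time_s + s.duration_ms / 1000.0 for s in specs) + pad_s
    wave = np.zeros(int(round(end_s * fs)))
    annotations: list[tuple[float, float, CallSpec]] = []
    peak_power = 0.0
    for spec in specs:
        note = synthesize_note(spec, fs, **synth_kwargs)
        i0 = int(round(spec.onset_time_s * fs))
        wave[i0:i0 + len(note)] += note
        # smoothed instantaneous power over a 0.5 ms window
        win = max(1, int(0.0005 * fs))
        power = np.convolve(note ** 2, np.ones(win) / win, mode="same")
        peak_power = max(peak_power, float(power.max()))
        annotations.append((spec.onset_time_s,
                            spec.onset_time_s + spec.duration_ms / 1000.0,
                            spec))
    snr_db = min(s.snr_db for s in specs)
    if math.isfinite(snr_db):
        if rng is None:
            rng = np.random.default_rng()
        sigma = math.sqrt(peak_power / 10.0 ** (snr_db / 10.0))
        wave = wave + rng.normal(0.0, sigma, len(wave))
    return AnnotatedRecording(wave, fs, annotations)


# ---------------------------------------------------------------------------
# dataset writing

ANNOTATION_COLUMNS = [
    "file", "start_s", "end_s", "species", "population", "colony",
    "individual", "sex", "session", "call_id", "note_index", "duration_ms",
    "inter_note_interval_ms", "snr_db",
]


def _truth_columns(spec: CallSpec) -> dict[str, float]:
    cols = {f"true_f0@{p:g}_khz": f for p, f in spec.f0_anchors_khz}
    for k, off in enumerate(spec.harmonic_offsets_db, start=1):
        cols[f"true_h{k}_db"] = off
    return cols


def write_dataset(
    specs: list[CallSpec],
    out_dir: str | Path,
    *,
    sampling_rate_hz: int = DEFAULT_SAMPLING_RATE,
    seed: int = 0,
    amplitude: float = 0.5,
    **synth_kwargs,
) -> pd.DataFrame:
    """Write one WAV per individual recording session plus annotations.csv.

    Returns the annotation table.  Fully reproducible: the noise stream
    of each recording is seeded from ``seed`` and the recording's index.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    by_recording: dict[tuple, list[CallSpec]] = {}
    for spec in specs:
        by_recording.setdefault((spec.individual, spec.session), []).append(spec)

    rows: list[dict] = []
    for idx, (key, rec_specs) in enumerate(sorted(by_recording.items())):
        indiv, session = key
        fname = f"{indiv}_{session}.wav"
        rng = np.random.default_rng(np.random.SeedSequence([seed, idx]))
        rec = render_recording(rec_specs, sampling_rate_hz, rng=rng,
                               **synth_kwargs)
        scaled = rec.waveform / max(1e-12, np.abs(rec.waveform).max()) * amplitude
        pcm = np.clip(np.round(scaled * 32767.0), -32768, 32767).astype(np.int16)
        try:
            wavfile.write(out / fname, sampling_rate_hz, pcm)
        except OSError as exc:
            raise OSError(f"failed writing {out / fname}: {exc}") from exc
        for start, end, spec in rec.annotations:
            row = {"file": fname, "start_s": round(start, 6),
                   "end_s": round(end, 6), **spec.labels,
                   "duration_ms": spec.duration_ms,
                   "inter_note_interval_ms": spec.inter_note_interval_ms,
                   "snr_db": spec.snr_db}
            row.update(_truth_columns(spec))
            rows.append(row)

    truth_cols = sorted({c for r in rows for c in r} - set(ANNOTATION_COLUMNS))
    table = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS + truth_cols)
    table.to_csv(out / "annotations.csv", index=False, float_format="%.6f")
    return table
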