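"""Spectrogram computation and per-note acoustic measurements.

The measurement set per note (36 values) comprises: duration; the
fundamental frequency at 10 relative positions (start through 90% of
the note); frequency of most energy (FME) of the fundamental and first
three harmonics; the time of each FME relative to note start; the slope
of the fundamental at 7 positions (20-80%); its concavity at the same
positions; and the intensity of each harmonic relative to the
fundamental.  Spectrograms use short Blackman windows zero-padded to a
fixed FFT length with 50% overlap, giving a fine frequency grid; the
fundamental contour is tracked by band-limited peak picking with a
continuity constraint and parabolic sub-bin refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal


@dataclass(frozen=True)
class SpectrogramParams:
    """Analysis parameters: 0.5 ms Blackman windows, 512-point FFT
    (488 Hz bins at 250 kHz sampling), 50% overlap."""

    window_ms: float = 0.5
    window_type: str = "blackman"
    fft_points: int = 512
    overlap_fraction: float = 0.5

    def window_samples(self, sampling_rate_hz: float) -> int:
        return max(2, int(round(self.window_ms / 1000.0 * sampling_rate_hz)))

    def validate(self, sampling_rate_hz: float) -> None:
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.window_samples(sampling_rate_hz) > self.fft_points:
            raise ValueError(
                "window longer than fft_points; zero-padding requires "
                "window samples <= fft_points")


@dataclass
class Spectrogram:
    """Magnitude spectrogram with frame-center times and bin frequencies."""

    magnitude: np.ndarray  # (frames, bins)
    frame_times_s: np.ndarray
    bin_freqs_hz: np.ndarray

    @property
    def bin_spacing_hz(self) -> float:
        return float(self.bin_freqs_hz[1] - self.bin_freqs_hz[0])

    def frames_in(self, start_s: float, end_s: float) -> np.ndarray:
        """Indices of frames whose centers lie in [start_s, end_s)."""
        return np.nonzero((self.frame_times_s >= start_s)
                          & (self.frame_times_s < end_s))[0]


TRACK_POSITIONS = np.round(np.arange(10) * 0.1, 1)  # 0.0 .. 0.9


@dataclass
class FundamentalTrack:
    """Fundamental contour on the relative-position grid (kHz)."""

    positions: np.ndarray
    freqs_khz: np.ndarray
    confidence: np.ndarray
    frame_times_s: np.ndarray = field(default=None)  # type: ignore[assignment]
    frame_freqs_khz: np.ndarray = field(default=None)  # type: ignore[assignment]
    low_confidence: bool = False

    def at(self, position: float | np.ndarray) -> np.ndarray:
        """Contour frequency at arbitrary relative positions (linear)."""
        return np.interp(position, self.positions, self.freqs_khz)


def compute_spectrogram(
    waveform: np.ndarray,
    sampling_rate_hz: float,
    params: SpectrogramParams | None = None,
) -> Spectrogram:
    """Magnitude spectrogram with the configured window geometry."""
    params = params or SpectrogramParams()
    params.validate(sampling_rate_hz)
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1 or waveform.size == 0:
        raise ValueError("waveform must be a non-empty 1-D array")
    nwin = params.window_samples(sampling_rate_hz)
    if waveform.size < nwin:
        raise ValueError(
            f"waveform ({waveform.size} samples) shorter than one "
            f"analysis window ({nwin} samples)")
    noverlap = int(nwin * params.overlap_fraction)
    win = signal.get_window(params.window_type, nwin)
    freqs, times, sxx = signal.spectrogram(
        waveform, fs=sampling_rate_hz, window=win, nperseg=nwin,
        noverlap=noverlap, nfft=params.fft_points, mode="magnitude",
        detrend=False)
    return Spectrogram(magnitude=sxx.T, frame_times_s=times,
                       bin_freqs_hz=freqs)


# ---------------------------------------------------------------------------
# fundamental tracking


def _parabolic_refine(mag: np.ndarray, idx: int) -> float:
    """Sub-bin peak offset from a 3-point parabola on log magnitude."""
    if idx <= 0 or idx >= len(mag) - 1:
        return 0.0
    eps = 1e-12
    a, b, c = (np.log(mag[idx - 1] + eps), np.log(mag[idx] + eps),
               np.log(mag[idx + 1] + eps))
    denom = a - 2 * b + c
    if denom >= -1e-15:
        return 0.0
    return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))


def _lowest_adequate_peak(mags: np.ndarray, rel_threshold: float) -> int:
    """Lowest-frequency local maximum at least ``rel_threshold`` of the
    strongest in-band cell.  The fundamental of a harmonic stack is the
    lowest partial, not necessarily the loudest (harmonics can carry
    more energy than the fundamental in these calls)."""
    floor = rel_threshold * mags.max()
    candidates = np.nonzero(
        (mags >= floor)
        & (np.r_[True, mags[1:] >= mags[:-1]])
        & (np.r_[mags[:-1] >= mags[1:], True]))[0]
    if candidates.size == 0:
        return int(np.argmax(mags))
    return int(candidates[0])


def track_fundamental(
    spect: Spectrogram,
    note: tuple[float, float],
    search_band_khz: tuple[float, float] = (8.0, 45.0),
    *,
    max_jump_bins: int = 3,
    rel_threshold: float = 0.25,
    noise_floor_factor: float = 4.0,
) -> FundamentalTrack:
    """Track the fundamental through a note by constrained peak picking.

    The anchor frame (strongest in-band energy) picks the lowest local
    maximum within ``rel_threshold`` of its in-band peak magnitude (the
    fundamental, even when a harmonic inside the band is louder); the
    track then propagates outward, restricting each frame's peak search
    to within ``max_jump_bins`` of the neighbouring frame's peak, with
    3-point parabolic interpolation for sub-bin precision.  The
    per-frame track is resampled to the 10% relative-position grid by
    linear interpolation in time; the value at position 0 is
    extrapolated from the first two analyzable frames (the first frame
    center sits half a window into the note).
    """
    start_s, end_s = note
    lo_khz, hi_khz = search_band_khz
    if hi_khz <= lo_khz:
        raise ValueError("empty search band")
    band = np.nonzero((spect.bin_freqs_hz >= lo_khz * 1000.0)
                      & (spect.bin_freqs_hz <= hi_khz * 1000.0))[0]
    if band.size == 0:
        raise ValueError("search band contains no frequency bins")
    frames = spect.frames_in(start_s, end_s)
    if frames.size == 0:
        raise ValueError("note interval contains no spectrogram frames")

    sub = spect.magnitude[np.ix_(frames, band)]
    n_frames = sub.shape[0]
    peak_bin = np.full(n_frames, -1, dtype=int)
    anchor = int(np.unravel_index(np.argmax(sub), sub.shape)[0])
    peak_bin[anchor] = _lowest_adequate_peak(sub[anchor], rel_threshold)
    for i in range(anchor + 1, n_frames):
        lo = max(0, peak_bin[i - 1] - max_jump_bins)
        hi = min(sub.shape[1], peak_bin[i - 1] + max_jump_bins + 1)
        peak_bin[i] = lo + int(np.argmax(sub[i, lo:hi]))
    for i in range(anchor - 1, -1, -1):
        lo = max(0, peak_bin[i + 1] - max_jump_bins)
        hi = min(sub.shape[1], peak_bin[i + 1] + max_jump_bins + 1)
        peak_bin[i] = lo + int(np.argmax(sub[i, lo:hi]))

    dbin = spect.bin_spacing_hz
    frame_freqs = np.empty(n_frames)
    confidence = np.empty(n_frames)
    floors = np.median(sub, axis=1)
    for i in range(n_frames):
        j = peak_bin[i]
        offset = _parabolic_refine(sub[i], j)
        frame_freqs[i] = (spect.bin_freqs_hz[band[j]] + offset * dbin) / 1000.0
        confidence[i] = sub[i, j] / (noise_floor_factor * floors[i] + 1e-12)
    low_conf = float(np.mean(confidence < 1.0)) > 0.30

    # resample to the relative-position grid with end extrapolation
    duration = end_s - start_s
    rel_frames = (spect.frame_times_s[frames] - start_s) / duration
    track = np.empty(TRACK_POSITIONS.size)
    for k, p in enumerate(TRACK_POSITIONS):
        if n_frames == 1:
            track[k] = frame_freqs[0]
        elif p < rel_frames[0]:
            slope = (frame_freqs[1] - frame_freqs[0]) / (rel_frames[1] - rel_frames[0])
            track[k] = frame_freqs[0] + slope * (p - rel_frames[0])
        elif p > rel_frames[-1]:
            slope = ((frame_freqs[-1] - frame_freqs[-2])
                     / (rel_frames[-1] - rel_frames[-2]))
            track[k] = frame_freqs[-1] + slope * (p - rel_frames[-1])
        else:
            track[k] = np.interp(p, rel_frames, frame_freqs)
    conf_grid = np.interp(TRACK_POSITIONS, rel_frames, confidence)
    return FundamentalTrack(
        positions=TRACK_POSITIONS.copy(), freqs_khz=track,
        confidence=conf_grid, frame_times_s=spect.frame_times_s[frames],
        frame_freqs_khz=frame_freqs, low_confidence=low_conf)


# ---------------------------------------------------------------------------
# the measurement vector

SLOPE_POSITIONS = np.round(np.arange(0.2, 0.81, 0.1), 1)  # 20..80%

FEATURE_COLUMNS: list[str] = (
    ["duration_ms"]
    + [f"f0@{p:g}_khz" for p in TRACK_POSITIONS]
    + [f"fme_h{k}_khz" for k in range(4)]
    + [f"t_fme_h{k}_ms" for k in range(4)]
    + [f"slope@{p:g}_khz_ms" for p in SLOPE_POSITIONS]
    + [f"concavity@{p:g}_khz_ms2" for p in SLOPE_POSITIONS]
    + [f"relint_h{k}_db" for k in (1, 2, 3)]
)
assert len(FEATURE_COLUMNS) == 36

LABEL_COLUMNS = ["species", "population", "colony", "individual", "sex",
                 "session", "call_id", "note_index"]


def slope_at(track: FundamentalTrack, position: float, duration_ms: float,
             step: float = 0.1) -> float:
    """Central-difference slope of the fundamental (kHz/ms) at a
    relative position; usable at any interior position, not only the
    canonical 20-80% grid."""
    f_hi = track.at(position + step)
    f_lo = track.at(position - step)
    return float((f_hi - f_lo) / (2 * step * duration_ms))


def concavity_at(track: FundamentalTrack, position: float, duration_ms: float,
                 step: float = 0.1) -> float:
    """Second central difference of the fundamental (kHz/ms^2)."""
    f = track.at(np.array([position - step, position, position + step]))
    return float((f[0] - 2 * f[1] + f[2]) / (step * duration_ms) ** 2)


def extract_features(
    spect: Spectrogram,
    track: FundamentalTrack,
    note: tuple[float, float],
    *,
    n_harmonics: int = 3,
    labels: dict | None = None,
    inter_note_interval_ms: float | None = None,
) -> dict:
    """Compute the 36-value measurement vector for one note.

    Harmonic bands per frame are ``(k+1)*f0(t) +/- f0(t)/2`` (bands tile
    the spectrum without overlap); the FME of a partial is the frequency
    of the maximum-magnitude time-frequency cell within its band over
    the whole note.  A harmonic whose band lies above Nyquist at every
    frame has its fields set to NaN.
    """
    start_s, end_s = note
    duration_ms = (end_s - start_s) * 1000.0
    frames = spect.frames_in(start_s, end_s)
    if frames.size == 0:
        raise ValueError("note interval contains no spectrogram frames")
    nyq_hz = float(spect.bin_freqs_hz[-1])
    times = spect.frame_times_s[frames]
    rel = (times - start_s) / (end_s - start_s)
    f0_khz = track.at(np.clip(rel, 0.0, 0.9))

    out: dict[str, float] = {"duration_ms": duration_ms}
    for p in TRACK_POSITIONS:
        out[f"f0@{p:g}_khz"] = float(track.at(p))

    peak_mag = np.full(n_harmonics + 1, np.nan)
    for k in range(n_harmonics + 1):
        center_hz = (k + 1) * f0_khz * 1000.0
        half_hz = f0_khz * 500.0
        best = (-np.inf, np.nan, np.nan)  # magnitude, freq_khz, time_ms
        for i, frame in enumerate(frames):
            lo = center_hz[i] - half_hz[i]
            hi = min(center_hz[i] + half_hz[i], nyq_hz)
            if lo >= nyq_hz:
                continue
            bins = np.nonzero((spect.bin_freqs_hz >= lo)
                              & (spect.bin_freqs_hz <= hi))[0]
            if bins.size == 0:
                continue
            mags = spect.magnitude[frame, bins]
            j = int(np.argmax(mags))
            if mags[j] > best[0]:
                offset = _parabolic_refine(spect.magnitude[frame], bins[j])
                freq = (spect.bin_freqs_hz[bins[j]]
                        + offset * spect.bin_spacing_hz) / 1000.0
                best = (float(mags[j]), freq, (times[i] - start_s) * 1000.0)
        if np.isfinite(best[0]):
            peak_mag[k] = best[0]
            out[f"fme_h{k}_khz"] = best[1]
            out[f"t_fme_h{k}_ms"] = best[2]
        else:
            out[f"fme_h{k}_khz"] = np.nan
            out[f"t_fme_h{k}_ms"] = np.nan

    for p in SLOPE_POSITIONS:
        out[f"slope@{p:g}_khz_ms"] = slope_at(track, p, duration_ms)
    for p in SLOPE_POSITIONS:
        out[f"concavity@{p:g}_khz_ms2"] = concavity_at(track, p, duration_ms)

    for k in (1, 2, 3):
        if k <= n_harmonics and np.isfinite(peak_mag[k]) and peak_mag[0] > 0:
            out[f"relint_h{k}_db"] = float(
                20.0 * np.log10(peak_mag[k] / peak_mag[0]))
        else:
            out[f"relint_h{k}_db"] = np.nan

    if labels:
        out.update(labels)
    out["inter_note_interval_ms"] = (
        np.nan if inter_note_interval_ms is None else inter_note_interval_ms)
    out["track_low_confidence"] = track.low_confidence
    return out


def amplitude_ok(waveform_segment: np.ndarray, full_scale: float = 1.0,
                 lo: float = 0.10, hi: float = 0.99) -> bool:
    """Unclipped, adequate-amplitude screen: peak |sample| must fall
    within [10%, 99%] of full scale."""
    peak = float(np.abs(waveform_segment).max())
    return lo * full_scale <= peak <= hi * full_scale


def extract_table(
    annotations: pd.DataFrame,
    wav_dir,
    params: SpectrogramParams | None = None,
    *,
    search_band_khz: tuple[float, float] = (8.0, 45.0),
    n_harmonics: int = 3,
    amplitude_screen: bool = True,
) -> pd.DataFrame:
    """Extract features for every annotated note in a dataset.

    ``annotations`` is the table written by :func:`callsig.synth.write_dataset`
    (columns ``file, start_s, end_s`` plus label columns); one row of
    measurements is returned per retained note.  Notes failing the
    amplitude screen are dropped with a ``dropped_reason`` recorded in
    ``extract_table.last_report``.
    """
    from pathlib import Path
    from scipy.io import wavfile

    params = params or SpectrogramParams()
    wav_dir = Path(wav_dir)
    rows, dropped = [], []
    for fname, group in annotations.groupby("file", sort=True):
        fs, pcm = wavfile.read(wav_dir / fname)
        wave = pcm.astype(float) / 32768.0
        spect = compute_spectrogram(wave, fs, params)
        for _, ann in group.iterrows():
            note = (float(ann["start_s"]), float(ann["end_s"]))
            seg = wave[int(note[0] * fs):int(note[1] * fs)]
            if amplitude_screen and not amplitude_ok(seg):
                dropped.append({"file": fname, "start_s": note[0],
                                "reason": "amplitude outside 10-99% of full scale"})
                continue
            track = track_fundamental(spect, note, search_band_khz)
            labels = {c: ann[c] for c in LABEL_COLUMNS if c in ann}
            labels["file"] = fname
            labels["t_onset_s"] = note[0]
            interval = ann.get("inter_note_interval_ms")
            interval = None if pd.isna(interval) else float(interval)
            rows.append(extract_features(
                spect, track, note, n_harmonics=n_harmonics, labels=labels,
                inter_note_interval_ms=interval))
    extract_table.last_report = pd.DataFrame(dropped)  # type: ignore[attr-defined]
    cols = FEATURE_COLUMNS + LABEL_COLUMNS + ["file", "t_onset_s",
                                              "inter_note_interval_ms",
                                              "track_low_confidence"]
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(columns=cols)
    return table[[c for c in cols if c in table.columns]]
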