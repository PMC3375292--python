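"""Species-typical contact-call profiles.

A :class:`SpeciesProfile` holds the parameters of a species' typical
downward frequency-modulated contact-call note: duration, a set of
fundamental-frequency anchors along the note, relative harmonic
amplitudes, and the note-count structure of calls.  The three built-in
profiles correspond to the three vampire bat species (common,
white-winged, and hairy-legged vampire bats), parameterized from
published per-species means of the acoustic variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SpeciesProfile:
    """Ground-truth acoustic parameters of a species-typical note.

    Parameters
    ----------
    name
        Species label carried into generated annotations.
    duration_ms
        Mean note duration in milliseconds.
    f0_anchors_khz
        Ordered ``(relative_position, frequency_khz)`` pairs describing
        the fundamental contour.  Positions must include 0 and 1; the
        frequencies must be strictly decreasing through at least the
        0.9 position (the note is a downward FM sweep).
    harmonic_offsets_db
        Amplitudes of harmonics 1-3 relative to the fundamental, in dB.
    notes_per_call_dist
        Probability of a call containing 1, 2, or 3 notes,
        as a mapping ``{1: p1, 2: p2, 3: p3}``.
    inter_note_interval_ms
        Mean silent interval between successive notes of a multi-note
        call (offset of one note to onset of the next).
    """

    name: str
    duration_ms: float
    f0_anchors_khz: tuple[tuple[float, float], ...]
    harmonic_offsets_db: tuple[float, float, float]
    notes_per_call_dist: dict[int, float] = field(
        default_factory=lambda: {1: 1.0}
    )
    inter_note_interval_ms: float = 21.5

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.f0_anchors_khz]
        if positions != sorted(positions):
            raise ValueError("f0 anchors must be ordered by relative position")
        if positions[0] != 0.0 or positions[-1] != 1.0:
            raise ValueError("f0 anchor positions must include 0 and 1")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        freqs_to_90 = [f for p, f in self.f0_anchors_khz if p <= 0.9 + 1e-9]
        if any(b >= a for a, b in zip(freqs_to_90, freqs_to_90[1:])):
            raise ValueError(
                "fundamental anchors must be strictly decreasing up to the "
                "90% position (downward FM sweep)"
            )
        total = sum(self.notes_per_call_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("notes_per_call_dist probabilities must sum to 1")

    @property
    def anchor_positions(self) -> tuple[float, ...]:
        return tuple(p for p, _ in self.f0_anchors_khz)

    @property
    def anchor_freqs_khz(self) -> tuple[float, ...]:
        return tuple(f for _, f in self.f0_anchors_khz)

    def max_frequency_khz(self, n_partials: int = 4) -> float:
        """Highest instantaneous frequency of the requested partials."""
        return max(self.anchor_freqs_khz) * n_partials


def _end_anchor(f50: float, f90: float) -> float:
    # Continue the 50->90% descent at 40% of its rate through the final
    # 10% of the note, keeping the sweep monotone to the end.
    return f90 - 0.1 * (f50 - f90)


# Per-species means: duration, fundamental at start/50%/90%, relative
# harmonic amplitudes.  Common vampire bats give short, steep, high calls
# with harmonics above the fundamental; white-winged vampire bats long,
# shallow, fundamental-dominated double-note calls; hairy-legged vampire
# bats the lowest-frequency calls with strong harmonics.

DESMODUS = SpeciesProfile(
    name="Desmodus",
    duration_ms=9.1,
    f0_anchors_khz=(
        (0.0, 36.2),
        (0.5, 23.4),
        (0.9, 19.3),
        (1.0, _end_anchor(23.4, 19.3)),
    ),
    harmonic_offsets_db=(6.6, 6.6, -1.1),
    notes_per_call_dist={1: 0.81, 2: 0.15, 3: 0.04},
    inter_note_interval_ms=21.5,
)

DIAEMUS = SpeciesProfile(
    name="Diaemus",
    duration_ms=18.6,
    f0_anchors_khz=(
        (0.0, 25.7),
        (0.5, 20.9),
        (0.9, 17.3),
        (1.0, _end_anchor(20.9, 17.3)),
    ),
    harmonic_offsets_db=(-2.8, -4.3, -18.8),
    notes_per_call_dist={1: 0.09, 2: 0.75, 3: 0.16},
    inter_note_interval_ms=21.5,
)

DIPHYLLA = SpeciesProfile(
    name="Diphylla",
    duration_ms=11.5,
    f0_anchors_khz=(
        (0.0, 20.8),
        (0.5, 16.5),
        (0.9, 12.6),
        (1.0, _end_anchor(16.5, 12.6)),
    ),
    harmonic_offsets_db=(9.9, 9.7, 1.0),
    notes_per_call_dist={1: 0.87, 2: 0.10, 3: 0.03},
    inter_note_interval_ms=21.5,
)

SPECIES_PROFILES: dict[str, SpeciesProfile] = {
    "Desmodus": DESMODUS,
    "Diaemus": DIAEMUS,
    "Diphylla": DIPHYLLA,
}
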