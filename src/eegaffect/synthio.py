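"""Seeded synthetic 62-channel EEG with class-dependent band-power structure.

Stands in for a wearable sensor / public EEG corpus: each emotion class is
characterized by a per-band variance profile, and recordings are sums of
independently band-limited Gaussian noise components whose realized
variance tracks the profile. The band filters are the same ones the
feature extractor uses, so generator and analyzer are mutually consistent.

Default profiles (uV^2 per band, delta..gamma):

* negative: elevated slow-wave power  (50, 50, 10, 10, 10)
* neutral:  flat                      (10, 10, 10, 10, 10)
* positive: elevated fast-wave power  (10, 10, 10, 50, 50)

Sub-seeding: recording ``i`` of a dataset draws its seed from entry ``i`` of
``numpy.random.SeedSequence(master_seed).generate_state(n)``, so datasets are
reproducible while recordings stay independent.
"""

from __future__ import annotations

from typing import Iterator, Optional, Sequence

import numpy as np
from scipy import signal

from .core import CANONICAL_BANDS, N_CHANNELS, ClassProfile, RawRecording
from .features import band_sos

__all__ = [
    "DEFAULT_PROFILES",
    "default_profile",
    "generate_recording",
    "iter_dataset",
    "generate_dataset",
]

_BASE_VAR = 10.0
_ELEVATED_VAR = 50.0

DEFAULT_PROFILES: dict[int, ClassProfile] = {
    -1: ClassProfile(label=-1, band_variance=(_ELEVATED_VAR, _ELEVATED_VAR,
                                              _BASE_VAR, _BASE_VAR, _BASE_VAR)),
    0: ClassProfile(label=0, band_variance=(_BASE_VAR,) * 5),
    1: ClassProfile(label=1, band_variance=(_BASE_VAR, _BASE_VAR, _BASE_VAR,
                                            _ELEVATED_VAR, _ELEVATED_VAR)),
}


def default_profile(label: int) -> ClassProfile:
    """The module's documented default profile for an emotion label."""
    return DEFAULT_PROFILES[label]


# 62-entry 10-20-system channel layout; canonical order is loaded from the
# packaged listing in the io module.
def _channel_names() -> list[str]:
    from .io import canonical_channel_names

    return canonical_channel_names()


def generate_recording(
    profile: ClassProfile,
    duration: float,
    sample_rate: float,
    seed: int,
    n_channels: int = N_CHANNELS,
) -> RawRecording:
    """Synthesize one labeled recording of band-limited Gaussian noise.

    Each canonical band contributes filtered white noise rescaled per channel
    so its realized variance equals the profile's target for that band.
    Identical arguments produce bit-identical output.
    """
    if duration < 1.0:
        raise ValueError(f"duration must be >= 1 s, got {duration}")
    gamma_edge = CANONICAL_BANDS[-1].high
    if sample_rate < 2 * gamma_edge:
        raise ValueError(
            f"sample_rate {sample_rate} Hz is below the {2 * gamma_edge:.0f} Hz "
            f"Nyquist requirement for the gamma band ({gamma_edge:.0f} Hz)"
        )
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    data = np.zeros((n_channels, n))
    for band, var in zip(CANONICAL_BANDS, profile.variance_array()):
        sos = band_sos(band.low, band.high, sample_rate)
        # causal pass suffices for noise shaping; features use the zero-phase form
        component = signal.sosfilt(sos, rng.standard_normal((n_channels, n)), axis=1)
        std = component.std(axis=1, keepdims=True)
        std[std == 0] = 1.0
        data += component * (np.sqrt(var) / std)
    names = _channel_names() if n_channels == N_CHANNELS else [f"ch{i}" for i in range(n_channels)]
    return RawRecording(data=data, sample_rate=sample_rate,
                        channel_names=names, label=profile.label)


def _subseeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n)


def iter_dataset(
    n_per_class: int,
    duration: float = 180.0,
    sample_rate: float = 200.0,
    seed: int = 0,
    profiles: Optional[Sequence[ClassProfile]] = None,
) -> Iterator[RawRecording]:
    """Lazily yield ``3 * n_per_class`` recordings, class-blocked (-1, 0, +1).

    Streaming generation keeps peak memory at one recording; use
    :func:`generate_dataset` for an eager list.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    if profiles is None:
        profiles = [DEFAULT_PROFILES[lbl] for lbl in (-1, 0, 1)]
    subseeds = _subseeds(seed, len(profiles) * n_per_class)
    i = 0
    for profile in profiles:
        for _ in range(n_per_class):
            yield generate_recording(profile, duration, sample_rate, int(subseeds[i]))
            i += 1


def generate_dataset(
    n_per_class: int,
    duration: float = 180.0,
    sample_rate: float = 200.0,
    seed: int = 0,
    profiles: Optional[Sequence[ClassProfile]] = None,
) -> list[RawRecording]:
    """Eager list form of :func:`iter_dataset`."""
    return list(iter_dataset(n_per_class, duration, sample_rate, seed, profiles))
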