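"""Core data containers: multichannel recordings and frequency-band definitions."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: 10-20 montage labels of the 31-electrode active cap (Cz is the reference
#: and therefore not a data channel).
ELECTRODES_31 = [
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8", "FT9", "FC5", "FC1", "FC2",
    "FC6", "FT10", "T7", "C3", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6",
    "TP10", "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
]

#: Canonical EEG frequency bands (Hz).  The gamma band is open-ended in the
#: literature; here it is closed at 98 Hz, the upper edge of the broadband
#: anti-noise filter, and additionally capped below Nyquist for low sampling
#: rates (see :func:`canonical_bands`).
CANONICAL_BAND_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 98.0),
}

BAND_ORDER = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency interval ``(f_lo, f_hi)`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"invalid band {self.name!r}: need 0 < f_lo < f_hi, "
                f"got ({self.f_lo}, {self.f_hi})"
            )

    def geometric_center(self) -> float:
        return float(np.sqrt(self.f_lo * self.f_hi))


def canonical_bands(fs: float = 500.0) -> list[BandDefinition]:
    """The five canonical bands, with gamma's upper edge capped below Nyquist.

    Parameters
    ----------
    fs
        Sampling rate in Hz.  Bands whose lower edge lies at or above
        0.95 * Nyquist are dropped (they cannot be realized).
    """
    nyq = fs / 2.0
    bands = []
    for name in BAND_ORDER:
        lo, hi = CANONICAL_BAND_EDGES[name]
        hi = min(hi, 0.95 * nyq)
        if lo >= hi:
            continue
        bands.append(BandDefinition(name, lo, hi))
    return bands


def default_channel_labels(n_channels: int) -> list[str]:
    if n_channels == len(ELECTRODES_31):
        return list(ELECTRODES_31)
    return [f"CH{i + 1:02d}" for i in range(n_channels)]


@dataclass
class EEGRecording:
    """A channels x samples signal matrix with its acquisition metadata.

    ``data`` is microvolt-scale (arbitrary units); ``covariates`` carries
    per-subject scalars such as a medication dose; ``meta`` carries
    provenance (e.g. the generator seed for synthetic recordings).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] | None = None
    subject_id: str = ""
    group: str = ""
    covariates: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] < 2:
            raise ValueError("a recording needs at least 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_labels is None:
            self.channel_labels = default_channel_labels(self.data.shape[0])
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        """A copy of this recording carrying new signal data."""
        return replace(self, data=data, channel_labels=list(self.channel_labels))
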