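"""Synthetic resting-state EEG cohorts with controllable envelope coupling.

Each channel of each band is a phase-randomized band-limited carrier (white
noise filtered to the band and normalized to unit instantaneous amplitude)
multiplied by a constructed positive envelope

    E_ch(t) = sqrt(1 - c) * eps_ch(t) + sqrt(c) * m(t),

where m is a shared slow (< 1 Hz) positive modulator, eps_ch are
independent positive processes of the same construction, and c in [0, 1] is
the fraction of envelope variance shared across channels.  Burst events
(Poisson times, 250 ms raised-cosine gain bumps of height ``burst_gain``)
multiply the shared modulator, steering the skewness of connectivity
fluctuations.  Optional instantaneous linear channel mixing emulates volume
conduction, and white sensor noise is added last.  Generation is a pure
function of the seed.

Normalizing the carriers to unit instantaneous amplitude makes the Hilbert
envelope of each band signal track E_ch directly, so envelope correlation
between channels approaches c itself: c = 0 gives independent envelopes,
c = 1 a single shared envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _sig

from .preprocess import design_fir, apply_filter
from .recording import BAND_ORDER, EEGRecording, canonical_bands, default_channel_labels

#: Low-pass cutoff (Hz) of the slow positive modulators.
MODULATOR_CUTOFF = 0.7
#: Width (s) of one raised-cosine burst bump.
BURST_WIDTH = 0.25


def _as_band_map(value, bands) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {b.name: float(value.get(b.name, 0.0)) for b in bands}
        unknown = set(value) - {b.name for b in bands}
        if unknown:
            raise ValueError(f"unknown band names: {sorted(unknown)}")
        return out
    return {b.name: float(value) for b in bands}


@dataclass
class SubjectSpec:
    """Generation parameters for one synthetic subject.

    ``band_amplitude`` and ``envelope_coupling`` accept either a scalar
    (applied to every canonical band) or a per-band mapping; bands absent
    from an amplitude mapping are silent.
    """

    n_channels: int = 31
    fs: float = 500.0
    duration: float = 60.0
    band_amplitude: Mapping[str, float] | float = 1.0
    envelope_coupling: Mapping[str, float] | float = 0.3
    burst_rate: float = 0.2          # events / second
    burst_gain: float = 2.0          # multiplicative bump height, >= 1
    mixing_strength: float = 0.0     # fraction of instantaneous leakage
    noise_sd: float = 0.05           # white sensor noise, signal units
    seed: int = 0
    carrier_order: int | None = None  # FIR order for carrier shaping; default ~1 s

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration must be an integer sample count")
        for b in canonical_bands(self.fs):
            c = self.coupling_for(b.name)
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"envelope coupling for {b.name} must be in [0, 1]")
        if not 0.0 <= self.mixing_strength <= 1.0:
            raise ValueError("mixing_strength must be in [0, 1]")
        if self.burst_gain < 1.0:
            raise ValueError("burst_gain must be >= 1")
        if self.burst_rate < 0 or self.noise_sd < 0:
            raise ValueError("burst_rate and noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def coupling_for(self, band_name: str) -> float:
        return _as_band_map(self.envelope_coupling, canonical_bands(self.fs))[band_name]

    def amplitude_for(self, band_name: str) -> float:
        return _as_band_map(self.band_amplitude, canonical_bands(self.fs))[band_name]


@dataclass
class GroupSpec:
    """One cohort group: a label, a size and a shared SubjectSpec template.

    ``dose_mean``/``dose_sd`` optionally attach a dose-like covariate
    (truncated-normal, independent of the dynamics so the covariate screen's
    null behavior is testable)."""

    label: str
    n_subjects: int
    subject: SubjectSpec = field(default_factory=SubjectSpec)
    dose_mean: float | None = None
    dose_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("each group needs at least 1 subject")


@dataclass
class CohortSpec:
    groups: Sequence[GroupSpec] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")


def _slow_positive(rng: np.random.Generator, shape, fs: float) -> np.ndarray:
    """Rectified low-pass-filtered Gaussian noise, normalized to mean 1.

    The noise is generated with burn-in margins of several filter time
    constants on each side and trimmed after filtering, so edge transients
    (which would otherwise appear as a spurious shared envelope component
    across channels) never reach the output.
    """
    if np.isscalar(shape):
        shape = (int(shape),)
    n = shape[-1]
    burn = int(round(4.0 * fs / MODULATOR_CUTOFF))
    ext = shape[:-1] + (n + 2 * burn,)
    sos = _sig.butter(4, MODULATOR_CUTOFF, fs=fs, output="sos")
    x = _sig.sosfiltfilt(sos, rng.standard_normal(ext), axis=-1)[..., burn:burn + n]
    m = np.abs(x)
    return (m / m.mean(axis=-1, keepdims=True)).reshape(shape)


def _burst_profile(rng: np.random.Generator, n: int, fs: float,
                   rate: float, gain: float) -> np.ndarray:
    """Multiplicative gain trace: 1 plus raised-cosine bumps at Poisson times."""
    profile = np.ones(n)
    if rate <= 0 or gain <= 1.0:
        return profile
    n_events = rng.poisson(rate * n / fs)
    if n_events == 0:
        return profile
    width = max(int(round(BURST_WIDTH * fs)), 2)
    bump = (gain - 1.0) * _sig.windows.hann(width)
    starts = rng.integers(0, max(n - width, 1), size=n_events)
    for s in starts:
        profile[s:s + width] += bump[: n - s]
    return profile


def _unit_carrier(rng: np.random.Generator, n_channels: int, n: int,
                  f_lo: float, f_hi: float, fs: float, order: int) -> np.ndarray:
    """Phase-randomized band-limited carriers with near-unit instantaneous
    amplitude.

    Band-filtered white noise is amplitude-normalized (cos of its Hilbert
    phase) and re-filtered; two such passes flatten the intrinsic envelope
    enough that the imposed envelope dominates the measured one, while the
    carrier stays essentially band-limited.
    """
    h = design_fir(f_lo, f_hi, order, fs, "bandpass")
    x = apply_filter(rng.standard_normal((n_channels, n)), h)
    for _ in range(2):
        a = _sig.hilbert(x, axis=-1)
        mag = np.abs(a)
        x = np.real(a) / np.maximum(mag, 1e-12 * np.median(mag))
        x = apply_filter(x, h)
    return x


def random_mixing_matrix(n_channels: int, seed: int) -> np.ndarray:
    """Symmetric nonnegative row-normalized leakage matrix (off-diagonal part)."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(size=(n_channels, n_channels))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def generate_subject(
    spec: SubjectSpec,
    mixing_matrix: np.ndarray | None = None,
    subject_id: str = "",
    group: str = "",
    return_internals: bool = False,
):
    """One synthetic recording; a pure function of ``spec`` (and the fixed
    mixing matrix, which a cohort shares across its subjects).

    With ``return_internals`` also returns the per-band shared modulator
    traces and constructed envelopes, for generator-level diagnostics.
    """
    rng = np.random.default_rng(spec.seed)
    n, n_ch, fs = spec.n_samples, spec.n_channels, spec.fs
    order = spec.carrier_order if spec.carrier_order is not None else int(round(fs))
    data = np.zeros((n_ch, n))
    internals: dict[str, dict] = {"modulator": {}, "envelope": {}}
    for band in canonical_bands(fs):
        amp = spec.amplitude_for(band.name)
        c = spec.coupling_for(band.name)
        carrier = _unit_carrier(rng, n_ch, n, band.f_lo, band.f_hi, fs, order)
        m = _slow_positive(rng, n, fs) * _burst_profile(
            rng, n, fs, spec.burst_rate, spec.burst_gain)
        eps = _slow_positive(rng, (n_ch, n), fs)
        envelope = amp * (np.sqrt(1.0 - c) * eps + np.sqrt(c) * m)
        if amp != 0.0:
            data += envelope * carrier
        internals["modulator"][band.name] = m
        internals["envelope"][band.name] = envelope
    if spec.mixing_strength > 0.0:
        if mixing_matrix is None:
            mixing_matrix = random_mixing_matrix(n_ch, spec.seed)
        mix = (1.0 - spec.mixing_strength) * np.eye(n_ch) \
            + spec.mixing_strength * mixing_matrix
        data = mix @ data
    if spec.noise_sd > 0.0:
        data += spec.noise_sd * rng.standard_normal((n_ch, n))
    rec = EEGRecording(
        data=data, fs=fs, channel_labels=default_channel_labels(n_ch),
        subject_id=subject_id, group=group,
        meta={"seed": spec.seed, "generator": "eegdfc.synthgen"},
    )
    if return_internals:
        return rec, internals
    return rec


def generate_cohort(spec: CohortSpec) -> list[EEGRecording]:
    """One recording per subject, with deterministic per-subject seeds
    derived from the cohort seed and group/covariate labels attached."""
    root = np.random.SeedSequence(spec.seed)
    n_total = sum(g.n_subjects for g in spec.groups)
    children = root.spawn(n_total + 1)
    mix_seed = int(children[0].generate_state(1)[0] % 2**31)
    recordings: list[EEGRecording] = []
    idx = 0
    for g in spec.groups:
        mixing = None
        if g.subject.mixing_strength > 0.0:
            mixing = random_mixing_matrix(g.subject.n_channels, mix_seed)
        for k in range(g.n_subjects):
            child = children[1 + idx]
            sub_seed = int(child.generate_state(1)[0] % 2**31)
            sub_rng = np.random.default_rng(child)
            sub_spec = replace(g.subject, seed=sub_seed)
            rec = generate_subject(
                sub_spec, mixing_matrix=mixing,
                subject_id=f"{g.label}{k + 1:02d}", group=g.label,
            )
            if g.dose_mean is not None:
                dose = max(0.0, g.dose_mean + g.dose_sd * sub_rng.standard_normal())
                rec.covariates["chlorpromazine_equivalent"] = float(dose)
            recordings.append(rec)
            idx += 1
    return recordings
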