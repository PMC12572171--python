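"""Instantaneous amplitude correlation (IAC) from leakage-corrected envelopes.

The dynamic connectivity metric is the per-sample product of normalized
amplitude envelopes,

    IAC_ij(t) = E_i(t) * E_j(t),

where E is the Hilbert-envelope of the band-limited signal, z-scored over
time.  With z-score normalization, the time average of IAC_ij is exactly the
Pearson correlation of the two envelopes — the static amplitude-envelope
correlation (AEC) — which serves as an analytic oracle for the dynamic
metric.

Zero-lag signal leakage (volume conduction) inflates envelope correlation;
before envelope extraction each pair of analytic signals can be
orthogonalized per sample by discarding the component of one signal that is
collinear (zero phase lag) with the other.  Pairwise orthogonalization is
directional, so both directions are computed and their per-sample products
averaged, preserving the symmetry of IAC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .recording import BandDefinition

#: Relative floor applied to |x(t)| in the orthogonalization denominator.
DENOM_FLOOR = 1e-12


def analytic_signal(band_signal: np.ndarray) -> np.ndarray:
    """Complex analytic signal per channel (Hilbert transform construction)."""
    x = np.asarray(band_signal, dtype=float)
    return _sig.hilbert(x, axis=-1)


def analytic_envelope(band_signal: np.ndarray) -> np.ndarray:
    """Modulus of the analytic signal; nonnegative, tracks slow amplitude
    modulation of the band-limited carrier."""
    x = np.atleast_2d(np.asarray(band_signal, dtype=float))
    if np.any(x.std(axis=-1) == 0.0):
        raise ValueError("constant (zero-variance) channel has no defined envelope")
    env = np.abs(_sig.hilbert(x, axis=-1))
    return env.reshape(np.shape(band_signal))


def orthogonalize_pair(x_analytic: np.ndarray, y_analytic: np.ndarray) -> np.ndarray:
    """Per-sample removal of the component of ``y`` collinear with ``x``.

    Returns the real residual  imag( y(t) * conj(x(t)) / |x(t)| ),  whose
    modulus is the leakage-corrected envelope of y with respect to x.  For
    ``y`` proportional to ``x`` the residual vanishes identically.
    """
    x = np.asarray(x_analytic)
    y = np.asarray(y_analytic)
    if x.shape != y.shape:
        raise ValueError("analytic signals must have equal length")
    mag = np.abs(x)
    floor = DENOM_FLOOR * max(float(np.median(mag)), 1e-300)
    return np.imag(y * np.conj(x) / np.maximum(mag, floor))


def _standardize(env: np.ndarray, mode: str = "zscore", *, tol: float = 1e-12,
                 degenerate_to_zero: bool = False) -> np.ndarray:
    """Row-wise envelope normalization.

    ``zscore`` (default) gives mean 0, variance 1; ``mean`` divides by the
    time mean; ``none`` passes through.  Rows with (numerically) zero
    variance raise, unless ``degenerate_to_zero`` maps them to an all-zero
    row — used internally for fully-suppressed leakage residuals, which
    carry no amplitude dynamics and contribute zero correlation.
    """
    env = np.atleast_2d(np.asarray(env, dtype=float))
    if mode == "none":
        return env
    mu = env.mean(axis=-1, keepdims=True)
    if mode == "mean":
        if np.any(mu == 0.0):
            raise ValueError("zero-mean envelope cannot be mean-normalized")
        return env / mu
    if mode != "zscore":
        raise ValueError(f"unknown normalization mode {mode!r}")
    sd = env.std(axis=-1, keepdims=True)
    scale = np.maximum(np.abs(mu), 1.0)
    degenerate = sd <= tol * scale
    if np.any(degenerate) and not degenerate_to_zero:
        raise ValueError("zero-variance envelope cannot be z-scored")
    z = (env - mu) / np.where(degenerate, 1.0, sd)
    if degenerate_to_zero:
        z = np.where(degenerate, 0.0, z)
    return z


@dataclass
class EnvelopeSet:
    """Normalized envelopes (channels x retained samples) for one band.

    ``trim`` records how many edge samples were dropped at each end before
    normalization (filter-transient exclusion); with trim 0 the retained
    span is the full recording.
    """

    values: np.ndarray
    trim: int = 0
    band: str = ""
    subject_id: str = ""
    mode: str = "zscore"

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def normalize_envelope(envelope: np.ndarray, trim: int = 0, mode: str = "zscore",
                       **meta) -> EnvelopeSet:
    """Standardize each channel's envelope over the trimmed span."""
    env = np.atleast_2d(np.asarray(envelope, dtype=float))
    if np.any(env < 0):
        raise ValueError("envelopes must be nonnegative")
    if trim < 0 or 2 * trim >= env.shape[-1]:
        raise ValueError("trim must satisfy 0 <= trim < samples/2")
    span = env[:, trim:env.shape[-1] - trim]
    return EnvelopeSet(values=_standardize(span, mode), trim=trim, mode=mode, **meta)


def pair_index(n_channels: int) -> np.ndarray:
    """(P, 2) array of upper-triangle channel pairs, row-major order."""
    iu = np.triu_indices(n_channels, k=1)
    return np.column_stack(iu)


@dataclass
class IACTensor:
    """Per-sample connectivity for one band of one recording.

    Stored compactly as samples x pairs (upper triangle) with a pair index
    map; each sample reconstructs to a symmetric channels x channels matrix
    whose diagonal is excluded from all downstream statistics.
    """

    values: np.ndarray           # (n_samples, n_pairs)
    pairs: np.ndarray            # (n_pairs, 2)
    n_channels: int
    band: str = ""
    subject_id: str = ""
    trim: int = 0
    orthogonalized: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]

    def matrix_at(self, t: int) -> np.ndarray:
        """Symmetric adjacency matrix at sample ``t`` (diagonal NaN: excluded)."""
        m = np.full((self.n_channels, self.n_channels), np.nan)
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        m[i, j] = self.values[t]
        m[j, i] = self.values[t]
        return m

    def time_mean(self) -> np.ndarray:
        """Static-AEC limit: per-pair time average of the dynamic metric."""
        return self.values.mean(axis=0)


def compute_iac(envelopes: EnvelopeSet, **meta) -> IACTensor:
    """Per-sample Hadamard products of normalized envelopes for all pairs."""
    env = envelopes.values
    pairs = pair_index(env.shape[0])
    values = (env[pairs[:, 0]] * env[pairs[:, 1]]).T  # (samples, pairs)
    return IACTensor(
        values=values, pairs=pairs, n_channels=env.shape[0],
        band=meta.pop("band", envelopes.band),
        subject_id=meta.pop("subject_id", envelopes.subject_id),
        trim=envelopes.trim, orthogonalized=False, meta=meta,
    )


def iac_tensor(
    band_signal: np.ndarray,
    trim: int = 0,
    orthogonalize: bool = True,
    mode: str = "zscore",
    band: str | BandDefinition = "",
    subject_id: str = "",
) -> IACTensor:
    """Full IAC computation for one band-limited channels x samples matrix.

    With ``orthogonalize`` the product for pair (i, j) is the average of the
    two directed products z(|j orth i|)·z(|i|) and z(|i orth j|)·z(|j|),
    which keeps the tensor exactly symmetric.  Without it the metric reduces
    to plain normalized-envelope products.
    """
    band_name = band.name if isinstance(band, BandDefinition) else band
    x = np.atleast_2d(np.asarray(band_signal, dtype=float))
    n_ch, n = x.shape
    if n_ch < 2:
        raise ValueError("IAC requires at least 2 channels")
    if trim < 0 or 2 * trim >= n:
        raise ValueError("trim must satisfy 0 <= trim < samples/2")
    A = _sig.hilbert(x, axis=-1)
    sl = slice(trim, n - trim)
    if not orthogonalize:
        env = normalize_envelope(np.abs(A)[:, sl], trim=0, mode=mode)
        env.trim = trim
        tensor = compute_iac(env, band=band_name, subject_id=subject_id)
        tensor.trim = trim
        return tensor

    mag = np.abs(A)
    floor = DENOM_FLOOR * max(float(np.median(mag)), 1e-300)
    U = np.conj(A) / np.maximum(mag, floor)          # unit-phase conjugates
    Z = _standardize(mag[:, sl], mode, degenerate_to_zero=True)
    pairs = pair_index(n_ch)
    # pair column index for an ordered (i, j): lookup table
    col_of = np.zeros((n_ch, n_ch), dtype=int)
    col_of[pairs[:, 0], pairs[:, 1]] = np.arange(len(pairs))
    col_of[pairs[:, 1], pairs[:, 0]] = np.arange(len(pairs))
    values = np.zeros((n - 2 * trim, len(pairs)))
    # one reference channel at a time keeps peak memory at O(n_ch * samples)
    for i in range(n_ch):
        resid_env = np.abs(np.imag(A * U[i]))[:, sl]   # |ch orth i|, all ch
        directed = _standardize(resid_env, mode, degenerate_to_zero=True)
        others = np.arange(n_ch) != i
        contrib = 0.5 * directed[others] * Z[i]        # z(|j orth i|) z(|i|)
        values[:, col_of[i, others]] += contrib.T
    return IACTensor(
        values=values, pairs=pairs, n_channels=n_ch, band=band_name,
        subject_id=subject_id, trim=trim, orthogonalized=True,
        meta={"normalization": mode},
    )
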