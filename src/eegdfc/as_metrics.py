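"""Global average strength (aS) of the dynamic connectivity tensor and its
first- to fourth-order moment descriptors.

The per-sample connectivity matrix is collapsed to the node strengths
(mean connectivity of each channel to the others) and then to their grand
average aS(t) — one scalar per sample, equivalently the mean of all
upper-triangle entries.  The resulting time series is summarized by its
mean (mu), standard deviation (sigma), skewness (phi) and kurtosis (kappa),
characterizing the level, variability, asymmetry and tailedness of the
connectivity fluctuations.

Conventions: population (n-denominator) moments; kurtosis is reported in
the Pearson convention (Gaussian = 3) by default, with the excess value
carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as _st

from .dfc_core import IACTensor

CUMULANT_NAMES = ("mu", "sigma", "phi", "kappa")


def node_strength(iac_matrix: np.ndarray) -> np.ndarray:
    """Per-node strength: mean connectivity of node i to all j != i.

    The diagonal is excluded by construction (it may hold NaN or anything
    else; it is never read).
    """
    m = np.asarray(iac_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square connectivity matrix")
    n = m.shape[0]
    if n < 2:
        raise ValueError("node strength needs at least 2 channels")
    off = ~np.eye(n, dtype=bool)
    return np.where(off, m, 0.0).sum(axis=1) / (n - 1)


@dataclass
class ASSeries:
    """One average-strength scalar per retained sample for one band."""

    values: np.ndarray
    band: str = ""
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("aS series must be finite")

    def __len__(self) -> int:
        return len(self.values)


def average_strength_series(tensor: IACTensor) -> ASSeries:
    """aS(t): the grand average over channels of the per-sample node
    strengths, i.e. the mean of all upper-triangle entries at each sample."""
    return ASSeries(
        values=tensor.values.mean(axis=1),
        band=tensor.band,
        subject_id=tensor.subject_id,
    )


@dataclass
class CumulantVector:
    """(mu, sigma, phi, kappa) of one aS series.

    ``kappa`` follows the convention named in ``kurtosis_convention``
    ("pearson": Gaussian = 3, or "excess": Gaussian = 0); the other
    convention is always recoverable from ``kappa_excess``.  For a
    zero-variance series phi and kappa are NaN (undefined, flagged by
    ``moments_defined``), never silently zero.
    """

    mu: float
    sigma: float
    phi: float
    kappa: float
    kappa_excess: float
    band: str = ""
    subject_id: str = ""
    group: str = ""
    kurtosis_convention: str = "pearson"

    @property
    def moments_defined(self) -> bool:
        return np.isfinite(self.phi) and np.isfinite(self.kappa)

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id, "group": self.group, "band": self.band,
            "mu": self.mu, "sigma": self.sigma, "phi": self.phi, "kappa": self.kappa,
        }


def cumulants(series, kurtosis_convention: str = "pearson") -> CumulantVector:
    """Moment descriptors of an aS series (population denominators)."""
    if kurtosis_convention not in ("pearson", "excess"):
        raise ValueError("kurtosis_convention must be 'pearson' or 'excess'")
    if isinstance(series, ASSeries):
        x, band, sid, grp = series.values, series.band, series.subject_id, series.group
    else:
        x, band, sid, grp = np.asarray(series, dtype=float).ravel(), "", "", ""
    if len(x) < 4:
        raise ValueError("need at least 4 samples for fourth-order moments")
    mu = float(np.mean(x))
    sigma = float(np.std(x))
    if sigma <= 1e-15 * max(1.0, abs(mu)):
        phi = kappa_p = kappa_e = float("nan")
        sigma = 0.0
    else:
        phi = float(_st.skew(x, bias=True))
        kappa_p = float(_st.kurtosis(x, fisher=False, bias=True))
        kappa_e = kappa_p - 3.0
    kappa = kappa_p if kurtosis_convention == "pearson" else kappa_e
    return CumulantVector(mu=mu, sigma=sigma, phi=phi, kappa=kappa,
                          kappa_excess=kappa_e,
                          band=band, subject_id=sid, group=grp,
                          kurtosis_convention=kurtosis_convention)


def cumulant_table(vectors: Iterable[CumulantVector]) -> pd.DataFrame:
    """Tidy table: one row per subject x band with mu, sigma, phi, kappa."""
    rows = [v.as_dict() for v in vectors]
    return pd.DataFrame(rows, columns=["subject_id", "group", "band", *CUMULANT_NAMES])
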