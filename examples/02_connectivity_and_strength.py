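"""From a band-limited recording to per-sample connectivity and the aS series.

One synthetic subject is band-decomposed; for the alpha band the script
computes the per-sample instantaneous amplitude correlation (IAC) tensor —
one symmetric adjacency matrix per temporal sample — with and without
leakage-correcting orthogonalization, collapses it to the global average
strength aS(t), and summarizes that series by its four moment descriptors.
"""

from eegdfc import (
    PipelineConfig,
    SubjectSpec,
    average_strength_series,
    cumulants,
    generate_subject,
    iac_tensor,
)
from eegdfc.preprocess import band_decompose, standard_preprocess

rec = generate_subject(SubjectSpec(n_channels=12, fs=250.0, duration=20.0,
                                   envelope_coupling=0.4, mixing_strength=0.2,
                                   seed=11))
rec = standard_preprocess(rec)
bands = band_decompose(rec)

for orthogonalize in (False, True):
    tensor = iac_tensor(bands.bands["alpha"], orthogonalize=orthogonalize,
                        band="alpha", subject_id=rec.subject_id)
    series = average_strength_series(tensor)
    cv = cumulants(series)
    tag = "orthogonalized" if orthogonalize else "raw           "
    print(f"alpha, {tag}: {tensor.n_samples} samples x {tensor.n_pairs} pairs"
          f" | aS mu={cv.mu:.3f} sigma={cv.sigma:.3f}"
          f" phi={cv.phi:.2f} kappa={cv.kappa:.1f}")

# The raw aS mean is inflated by the instantaneous channel mixing (volume-
# conduction surrogate); orthogonalization removes the zero-lag collinear
# component, so its mu isolates genuine envelope coupling.  phi > 0 and
# kappa > 3 say connectivity fluctuations are right-skewed and heavy-tailed.
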