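"""Generate a small synthetic EEG cohort with known envelope coupling.

Two groups share every generation parameter except the beta-band envelope
coupling c — the fraction of each channel's slow amplitude-envelope
variance driven by a modulator common to all channels.  The printed
envelope correlations show that the generator turns c into measurable
between-channel coupling.
"""

import numpy as np
from scipy.signal import hilbert

from eegdfc import CohortSpec, GroupSpec, SubjectSpec, generate_cohort
from eegdfc.preprocess import apply_filter, design_fir

spec = CohortSpec(
    groups=[
        GroupSpec("HC", 3, SubjectSpec(n_channels=12, fs=250.0, duration=12.0,
                                       envelope_coupling={"delta": 0.3, "theta": 0.3,
                                                          "alpha": 0.3, "beta": 0.2,
                                                          "gamma": 0.3})),
        GroupSpec("SCZ", 3, SubjectSpec(n_channels=12, fs=250.0, duration=12.0,
                                        envelope_coupling={"delta": 0.3, "theta": 0.3,
                                                           "alpha": 0.3, "beta": 0.5,
                                                           "gamma": 0.3}),
                  dose_mean=800.0, dose_sd=400.0),
    ],
    seed=7,
)
recordings = generate_cohort(spec)
print(f"{len(recordings)} recordings, shape {recordings[0].data.shape} "
      f"at {recordings[0].fs:.0f} Hz")

beta_filter = design_fir(13.0, 30.0, order=500, fs=250.0)
for rec in recordings:
    env = np.abs(hilbert(apply_filter(rec.data, beta_filter), axis=-1))
    corr = np.corrcoef(env)[np.triu_indices(rec.n_channels, 1)].mean()
    dose = rec.covariates.get("chlorpromazine_equivalent")
    dose_txt = f", dose {dose:6.0f} mg/day" if dose is not None else ""
    print(f"  {rec.subject_id} ({rec.group}): mean beta envelope "
          f"correlation {corr:.3f}{dose_txt}")

# The SCZ rows should show visibly larger beta envelope correlation
# (coupling 0.5 vs 0.2); the dose column is drawn independently of the
# dynamics, so it carries no connectivity information by construction.
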