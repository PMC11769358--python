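"""Per-subject summary values reported for the 18-subject clinical cohort.

The translation method was originally evaluated on concurrent scalp /
foramen-ovale recordings from 18 temporal-lobe-epilepsy patients.  Those
recordings are not public, but the per-subject summary tables are, and this
package uses them in two roles: as calibration inputs for the synthetic
cohort generator (IED counts and scalp-visibility rates) and as reference
aggregates that the table utilities in :mod:`eegtranslate.mapping_eval`
reproduce.

All arrays are ordered S1..S18.
"""

import numpy as np

#: Total number of annotated IEDs per subject (annotated on the intracranial
#: recording, which serves as ground truth).
IED_COUNTS = np.array(
    [342, 50, 71, 165, 158, 472, 199, 317, 341, 224, 848, 953, 829, 536, 260, 606, 114, 118]
)

#: Number of those IEDs that were also visible on the scalp recording.
SCALP_VISIBLE_COUNTS = np.array(
    [129, 17, 9, 60, 19, 77, 45, 143, 46, 86, 90, 12, 35, 74, 28, 11, 28, 5]
)

#: Scalp-visible percentage per subject, as printed (one decimal place).
SCALP_VISIBLE_PERCENT = np.array(
    [37.7, 34.0, 12.7, 36.4, 12.0, 16.3, 22.6, 45.1, 13.5, 38.4,
     10.6, 1.3, 4.2, 13.8, 10.8, 1.8, 24.6, 4.2]
)

#: Mapping quality per subject (intra-subject protocol): mean squared error,
#: Pearson correlation and cosine similarity between real and estimated
#: intracranial segments.
MAPPING_MSE = np.array(
    [0.012, 0.012, 0.017, 0.013, 0.014, 0.014, 0.017, 0.022, 0.013,
     0.013, 0.015, 0.012, 0.014, 0.013, 0.015, 0.012, 0.013, 0.015]
)
MAPPING_PCORR = np.array(
    [0.48, 0.46, 0.21, 0.32, 0.33, 0.31, 0.22, 0.18, 0.38,
     0.32, 0.33, 0.53, 0.36, 0.42, 0.23, 0.46, 0.28, 0.22]
)
MAPPING_COSSIM = np.array(
    [0.47, 0.45, 0.21, 0.32, 0.33, 0.31, 0.21, 0.18, 0.37,
     0.32, 0.32, 0.53, 0.35, 0.41, 0.23, 0.45, 0.28, 0.21]
)

#: IED detection accuracy (percent) of the full translation + classification
#: pipeline, per subject: inter-subject (leave-one-subject-out, ensemble
#: average voting) and intra-subject (70/10/20 split) protocols.
INTER_SUBJECT_ACC = np.array(
    [71, 87, 77, 64, 67, 70, 62, 61, 68, 82, 60, 75, 67, 60, 55, 73, 69, 67]
)
INTRA_SUBJECT_ACC = np.array(
    [80, 95, 78, 74, 74, 74, 68, 72, 77, 90, 63, 84, 75, 72, 60, 86, 86, 67]
)
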