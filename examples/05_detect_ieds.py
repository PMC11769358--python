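"""Detect IEDs from translated segments: intra- and inter-subject protocols.

Trains a translation model and a compact convolutional classifier per subject
on a small synthetic cohort, evaluates each subject intra-subject (70/10/20
split), selects subjects with accuracy strictly above 70%, and scores one
held-out subject with the ensemble's average vote.  Takes a few minutes on
one CPU core.
"""

from eegtranslate.demo import (
    easy_cohort,
    recovery_arch,
    recovery_classifier_config,
    recovery_training_config,
)
from eegtranslate.ied_classifier import (
    CrossValidationPlan,
    inter_subject_eval,
    intra_subject_eval,
    select_training_subjects,
)
from eegtranslate.trainer import train_subject

cohort = easy_cohort(n_subjects=3, segments_per_subject=96, seed=0)
plan = CrossValidationPlan()

models, classifiers, intra_acc = {}, {}, {}
for rec in cohort.subjects:
    model, _ = train_subject(rec.segments, recovery_arch(),
                             recovery_training_config(seed=0))
    metrics, clf = intra_subject_eval(rec.segments, model, plan,
                                      recovery_classifier_config(seed=0),
                                      return_classifier=True)
    models[rec.subject_id], classifiers[rec.subject_id] = model, clf
    intra_acc[rec.subject_id] = metrics.ACC
    print(f"{rec.subject_id}: intra-subject ACC={metrics.ACC:.3f} "
          f"SEN={metrics.SEN:.3f} SPC={metrics.SPC:.3f} AUC={metrics.AUC:.3f}")

selected = select_training_subjects(intra_acc, plan.selection_threshold)
print(f"\nsubjects with ACC > {plan.selection_threshold:.0%}: {selected}")

test_subject = cohort.subjects[-1]
ensemble = {sid: (models[sid], classifiers[sid])
            for sid in selected if sid != test_subject.subject_id}
if ensemble:
    m = inter_subject_eval(test_subject.segments, ensemble)
    print(f"inter-subject (test {test_subject.subject_id}, N={len(ensemble)} voters): "
          f"ACC={m.ACC:.3f} SEN={m.SEN:.3f} SPC={m.SPC:.3f}")
# Sensitivity counts detected IEDs, specificity detected non-IEDs; the
# inter-subject score shows how well models trained on other subjects
# generalize to an unseen one via average voting.
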