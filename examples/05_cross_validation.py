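"""Compare the cross-clip and cross-subject evaluation protocols.

Cross-clip folds mix every subject's windows across train and validation, so
subject-specific amplitude levels leak into training; cross-subject folds
hold out whole subjects and measure generalisation to unseen people. The
cross-subject score is expected to be the lower of the two.
"""

from asft.evaluate import cross_clip_cv, cross_subject_cv
from asft.studies import small_eval_config, small_study_table

table = small_study_table(seed=4)
cfg = small_eval_config(seed=4)

clip = cross_clip_cv(table, cfg)
print(clip.summary())
subj = cross_subject_cv(table, cfg)
print(subj.summary())

gap = clip.mean_accuracy - subj.mean_accuracy
print(f"generalisation gap (cross-clip − cross-subject): {gap:+.3f}")
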