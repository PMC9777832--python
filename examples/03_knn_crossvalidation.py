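"""Emotion classification of one synthetic subject.

Generates a two-emotion recording where four of ten channels carry an
emotion-dependent regularity shift, extracts the ApEn/SampEn feature table
(one row per 1-s epoch, two columns per channel) and reports the ten-fold
cross-validated KNN (K=2, Euclidean) accuracy and confusion matrix.
"""

from entrochan import (KNNConfig, SynthConfig, cross_validate, epoch_segments,
                       extract_features, generate_subject)

cfg = SynthConfig(n_subjects=1, seed=7,
                  schedule=((0, 29, "calm"), (30, 59, "tense"),
                            (60, 89, "calm"), (90, 119, "tense")))
rec, ann, gt = generate_subject(cfg, 0)
print(f"subject: {rec.n_channels} channels, {rec.duration_s:.0f} s at "
      f"{rec.rate:.0f} Hz; informative channels: "
      f"{', '.join(gt.informative_channels)}")

table = extract_features(epoch_segments(rec, ann))
print(f"feature table: {table.n_epochs} epochs x {table.values.shape[1]} features")

cv = cross_validate(table, KNNConfig(k=2, seed=0))
print(f"\nmean 10-fold accuracy: {cv.mean_accuracy * 100:.2f}%")
print("\nconfusion matrix (rows = true emotion, % of row):")
print(cv.confusion.round(1).to_string())
print("\nAccuracy well above the 50% chance level shows the entropy features")
print("carry the planted regularity difference between the two emotions.")
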