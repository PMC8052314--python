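"""Map cannulation outcomes to difficulty labels and train a classifier.

A case is *difficult* when cannulation took over 5 minutes, needed an
additional technique (double guidewire, needle-knife fistulotomy, device
change), or failed.  The classifier predicts that from the image alone.
Takes a minute or two on one CPU.
"""

import numpy as np
from sklearn.model_selection import train_test_split

from ampulla import (
    ClassifierConfig,
    OutcomeRecord,
    SynthConfig,
    generate_dataset,
    map_outcome,
    train_difficulty_classifier,
    evaluate_classifier,
)

# the label rules on a few illustrative outcomes
for rec in [OutcomeRecord(130.0, False, True), OutcomeRecord(301.0, False, True),
            OutcomeRecord(400.0, True, True), OutcomeRecord(None, False, False)]:
    lab = map_outcome(rec)
    print(f"time={rec.cannulation_time_s} technique={rec.additional_technique} "
          f"success={rec.success} -> {lab.four_class} ({lab.binary})")

samples = generate_dataset(SynthConfig(n_images=300, image_size=32, seed=11))
ds = [(s.image, s.label) for s in samples]
idx_tr, idx_te = train_test_split(np.arange(len(ds)), test_size=0.25, random_state=0,
                                  stratify=[s.label.binary for s in samples])
clf = train_difficulty_classifier([ds[i] for i in idx_tr], "binary", "macro_f1",
                                  ClassifierConfig(seed=0, max_epochs=25))
report = evaluate_classifier(clf, [ds[i] for i in idx_te])
print(f"\nheld-out accuracy {report.accuracy:.3f}, macro-F1 {report.macro_f1:.3f}, "
      f"AUC {report.auc:.3f}")
for cls, m in report.per_class.items():
    print(f"  {cls:9s}: precision {m['precision']:.3f}  recall {m['recall']:.3f}  F1 {m['f1']:.3f}")
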