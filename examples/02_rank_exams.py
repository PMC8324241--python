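"""Train the abnormality ranker and evaluate its nDCG@k curve.

The ranker is a dense sigmoid head on the concatenated two-view embedding,
trained with binary cross-entropy.  nDCG@k (binary relevance, abnormal = 1)
is bootstrap-averaged over resamples of the test split and compared with a
uniformly random scorer — the no-screening baseline.
"""

import numpy as np

import radtriage as rt
from radtriage.nets import TrainConfig

config = rt.SynthConfig(n_exams=600, seed=0)
collection = rt.generate_collection(config, "scratch/demo_rank")
encoder = rt.make_small_cnn(config.image_size, 96, seed=0)
table = rt.encode_collection(collection, encoder)

x = lambda exams: table.subset([e.exam_id for e in exams]).matrix.astype(float)
y = lambda exams: np.array([e.is_abnormal for e in exams], dtype=float)
train, val, test = (collection.split(s) for s in ("train", "val", "test"))

model, history = rt.train_ranker(x(train), y(train), x(val), y(val),
                                 TrainConfig(seed=0, epochs=1000, hidden=(64,)))
print(f"final validation loss: {history['val_loss'][-1]:.4f}")

test_ids = [e.exam_id for e in test]
scores = model.net.predict_proba(x(test))[:, 0]
ks = range(10, 61)
curve = rt.bootstrap_curve(scores, y(test), test_ids, k_range=ks,
                           sample_size=60, seed=0)
rand = np.array([s.score for s in rt.random_ranker(test_ids, seed=0)])
rand_curve = rt.bootstrap_curve(rand, y(test), test_ids, k_range=ks,
                                sample_size=60, seed=0)
print(f"trained ranker  mean nDCG@k over k=10..60: {curve.values.mean():.3f}")
print(f"random ranker   mean nDCG@k over k=10..60: {rand_curve.values.mean():.3f}")
# values near 1 mean abnormal exams fill the top of the worklist; the random
# baseline reflects the abnormal fraction of the collection

ranked = rt.rank_exams(rt.score_collection(table.subset(test_ids), model))
print("\ntop 5 of the ranked worklist:")
for exam_id, score in ranked.top_k(5):
    print(f"  {exam_id}  score={score:.3f}  "
          f"abnormal={collection[exam_id].is_abnormal}")
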