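"""Generate a synthetic two-view radiography collection.

Each abnormal exam carries 1-5 abnormality tags; every tag renders a
geometric brightness motif into both views, and the exam's findings text is
composed from per-tag template sentences, so pixels, tags and text are
causally linked.  The manifest plus PNGs land in ./scratch/demo_dataset.
"""

from collections import Counter

import radtriage as rt

config = rt.SynthConfig(n_exams=200, seed=0)
collection = rt.generate_collection(config, "scratch/demo_dataset")

n_abnormal = sum(e.is_abnormal for e in collection)
print(f"exams: {len(collection)}  abnormal: {n_abnormal} "
      f"({n_abnormal / len(collection):.0%})")
print(f"vocabulary ({len(collection.vocabulary)} tags):",
      ", ".join(collection.vocabulary))
counts = Counter(len(e.gold_tags) for e in collection if e.is_abnormal)
print("tags per abnormal exam:", dict(sorted(counts.items())))

example = next(e for e in collection if e.is_abnormal)
print(f"\nexample exam {example.exam_id}")
print("  tags:   ", ", ".join(sorted(example.gold_tags)))
print("  caption:", example.gold_caption)
# a caption always names its exam's tags, so a keyword labeler can score
# retrieved captions against the gold tag set later on
labeler = rt.keyword_labeler(rt.default_lexicon())
print("  labeler recovers:", ", ".join(sorted(labeler(example.gold_caption))))
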