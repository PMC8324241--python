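"""The full triage pipeline: rank all test exams, tag the top-k, caption them.

Mirrors the intended clinical workflow — a worklist ordered by abnormality
probability, where only the highest-priority exams receive tags and an
explanatory findings text.  Outputs (ranked.tsv, tags.jsonl, captions.jsonl,
run_log.jsonl) are written under scratch/demo_pipeline/out.
"""

import radtriage as rt
from radtriage.pipeline import PipelineConfig, run_pipeline

config = rt.SynthConfig(n_exams=400, seed=0)
rt.generate_collection(config, "scratch/demo_pipeline/data")

result = run_pipeline(PipelineConfig(
    manifest="scratch/demo_pipeline/data/manifest.jsonl",
    out_dir="scratch/demo_pipeline/out",
    k=10, seed=0,
))

print(f"ranked {len(result.ranked)} test exams; "
      f"tagged and captioned the top {len(result.top_k)}")
print("\nrank  exam         score  predicted tags -> retrieved caption source")
for pos, (exam_id, score) in enumerate(result.top_k, start=1):
    tags = ", ".join(sorted(result.predicted_tags[exam_id])) or "(none)"
    cap = result.captions[exam_id]
    flag = "exact-tag match" if cap.constrained else "fallback"
    print(f"{pos:>4}  {exam_id}  {score:.3f}  [{tags}] -> "
          f"{cap.source_exam_id} ({flag})")
first = result.top_k[0][0]
print(f"\ncaption assigned to {first}:")
print(" ", result.captions[first].caption)
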