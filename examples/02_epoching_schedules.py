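"""Segment schedules and 1-s epoch bookkeeping.

Each musical piece is annotated with labelled time spans (integer seconds,
inclusive at both ends); every labelled second becomes one 500-sample epoch.
The bundled reference schedules reproduce the published per-emotion sample
sizes exactly.
"""

from entrochan import parse_annotations
from entrochan.reference import GROUPS, load_annotations

for group in GROUPS:
    ann = load_annotations(group)
    counts = ann.n_epochs()
    print(f"{group}: {len(ann.segments)} segments")
    for emotion, n in counts.items():
        print(f"  {emotion:<14}{n:>4} epochs")

print("\nA custom schedule uses the same dialect:")
ann = parse_annotations("0:43–0:52\tNervousness")
print("  '0:43–0:52 Nervousness' ->", ann.segments,
      "->", ann.n_epochs()["Nervousness"], "epochs (inclusive bounds)")
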