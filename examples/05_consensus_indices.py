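"""Cross-subject consensus from the bundled reference selection matrices.

Three groups of ten subjects each have a published per-subject optimal
channel mask.  Channels chosen by at least six of a group's ten subjects
form that group's common set; stacking all 30 subjects yields per-channel
strength (FRSOC) and breadth (OCSR) indices and the principal/weak channel
classification.
"""

from entrochan import channel_indices, classify_channels, common_channels
from entrochan.reference import GROUPS, load_selection, load_stacked_selection

for group in GROUPS:
    sel = load_selection(group)
    common = common_channels(sel, threshold=6)
    print(f"{group}: common set ({len(common)} channels): {', '.join(common)}")

stacked = load_stacked_selection()
idx = classify_channels(channel_indices(stacked))
print(f"\nstacked 30 subjects: total selections {idx.attrs['total']}, "
      f"average per channel {idx.attrs['average']:.1f}")
for cls in ("principal", "weak"):
    sub = idx[idx["class"] == cls]
    print(f"{cls} channels:")
    for ch, row in sub.iterrows():
        print(f"  {ch:<5} FRSOC {row['frsoc']:.3f}  OCSR {row['ocsr'] * 100:.1f}%")

print("\nFRSOC > 1 marks channels picked more often than average; OCSR is the")
print("fraction of subjects picking them.  Channels high on both (strength")
print("and breadth) are the principal emotion-responsive channels.")
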