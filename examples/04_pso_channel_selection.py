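"""PSO channel selection on a subject with planted informative channels.

A binary particle swarm (sigmoid-binarized positions, KNN-CV fitness)
searches the 2^10 channel subsets for the one that classifies best.  The
generator's ground truth tells us how many of the planted channels the
optimizer recovered.
"""

from entrochan import (PSOConfig, SynthConfig, epoch_segments,
                       extract_features, generate_subject, pso_select)

cfg = SynthConfig(n_subjects=1, seed=3)
rec, ann, gt = generate_subject(cfg, 0)
table = extract_features(epoch_segments(rec, ann))

mask, trace = pso_select(table, PSOConfig(n_particles=20, t_max=30, seed=3))

print(f"selected {mask.n_selected}/{len(mask.channels)} channels: "
      f"{', '.join(mask.selected)}")
print(f"best fitness (mean 10-fold CV accuracy): {mask.fitness * 100:.2f}%")
print(f"fitness evaluations (memoized): {trace.n_evaluations}")
print(f"global-best trace (first/last): {trace.best_fitness[0]:.3f} -> "
      f"{trace.best_fitness[-1]:.3f} over {len(trace.best_fitness)} iterations")

planted = set(gt.informative_channels)
found = planted & set(mask.selected)
print(f"\nplanted informative channels: {', '.join(sorted(planted))}")
print(f"recovered: {', '.join(sorted(found))} "
      f"(recall {len(found) / len(planted):.2f})")
print("\nThe trace never decreases (best-ever bookkeeping), and the mask")
print("concentrates on channels whose regularity actually encodes emotion.")
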