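"""Learn a binding-site matrix from occurrences and rescan with it.

Builds a position weight matrix from 50 ISRE-like site occurrences (10% of
them carrying a point substitution) by anchored-tuple alignment (tuple size
8, present in ≥60% of sites, inclusion at matrix similarity ≥0.9), then
scans independent simulated promoters and measures planted-site recovery.
"""

import synergyscan as ss
from synergyscan.motifs import TFClass, build_pwm, scan_promoters
from synergyscan.simulate import PlantSpec

train, _ = ss.simulate_promoters(
    50, length=40, window=(0, 40),
    planted=[PlantSpec(TFClass.ISRE, position=14)],
    mutation_rate=0.10, seed=91,
)
result = build_pwm(
    [seq for _, seq in train], name="isre_learned", tf_class=TFClass.ISRE,
    tuple_size=8, min_tuple_frac=0.60, mss_inclusion=0.90,
)
print(f"anchor 8-mer: {result.anchor}")
print(f"sites included at convergence: {len(result.included)}/50 "
      f"({result.n_iterations} iterations)")
print(f"learned consensus: {result.pwm.consensus} "
      f"(length {len(result.pwm)}, core at {result.pwm.core_positions})")

proms, truth = ss.simulate_promoters(
    40, length=1100, planted=[PlantSpec(TFClass.ISRE)],
    mutation_rate=0.10, seed=92,
)
hits = scan_promoters(proms, [result.pwm], min_core=0.85, min_mss=0.80)
planted = {(s.gene_id, s.start, s.end) for s in truth.planted_sites}
recovered = sum(
    any(h.gene_id == g and h.start < e and h.end > s for h in hits)
    for g, s, e in planted
)
false_hits = sum(
    not any(h.gene_id == g and h.start < e and h.end > s for g, s, e in planted)
    for h in hits
)
print(f"\nscan of 40 independent promoters: {len(hits)} hits")
print(f"planted sites recovered: {recovered}/40   false hits: {false_hits}")
print(
    "\nthe learned matrix spans only the conserved region (uninformative\n"
    "flanks are trimmed), so a mutated occurrence still scores ≈(L−1)/L."
)
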