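"""Intersect gene signatures across cohorts and test overlap enrichment.

Takes the amplified genes from the packaged published table, maps the
mouse/legacy symbols to human-style ones (Cxcl9 → CXCL9, MCP-5 → CCL12 via
the packaged alias list), intersects them with a mock plaque signature, and
tests the overlap with the exact one-tailed hypergeometric test.
"""

import synergyscan as ss
from synergyscan.plaque import GeneSet

fixture = ss.load_table1_fixture()
wt, ko = fixture.fold_tables()
table = ss.build_synergy_table(wt, ko, missing_p="significant")

amplified = ss.map_symbols(
    GeneSet.from_iterable("vsmc_amplified", (r.gene_id for r in table.amplified()))
)
# stand-in for a plaque cohort signature (synthetic, for illustration)
plaque_sig = GeneSet.from_iterable(
    "plaque", ["CXCL9", "CXCL10", "CCL5", "CCL12", "GBP5", "CD74", "UBD",
               "VCAM1", "ICAM1", "MMP9", "SPP1", "CD68"]
)

venn = ss.intersect_gene_sets([amplified, plaque_sig])
print(f"amplified VSMC genes (human symbols): {len(amplified)}")
print(f"plaque signature:                     {len(plaque_sig)}")
print(f"shared: {venn.intersection('vsmc_amplified', 'plaque')} "
      f"(only-amplified {venn.count('vsmc_amplified')}, "
      f"only-plaque {venn.count('plaque')})")

universe = GeneSet.from_iterable(
    "array", list(amplified.members | plaque_sig.members)
    + [f"GENE{i}" for i in range(500)]
)
res = ss.hypergeometric_enrichment(amplified, plaque_sig, universe)
print(
    f"\nenrichment: overlap {res.overlap}, fold {res.fold_enrichment:.1f}, "
    f"P = {res.p_value:.2e}"
)
print(
    "\nP is the exact upper-tail probability of seeing at least this overlap\n"
    "if the signature were drawn at random from the array universe."
)
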