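import numpy as np
import pandas as pd
import pytest

from synergyscan.io import (
    Condition,
    ConditionDesign,
    ExpressionMatrix,
    Genotype,
    SampleInfo,
)


def make_design(n_reps: int = 3, genotypes=(Genotype.WT, Genotype.KO)) -> ConditionDesign:
    samples = [
        SampleInfo(f"{g.value}_{c.value}_{r}", g, c, r)
        for g in genotypes
        for c in Condition
        for r in range(1, n_reps + 1)
    ]
    return ConditionDesign(samples)


@pytest.fixture
def design_2x4x3() -> ConditionDesign:
    return make_design()


@pytest.fixture
def small_matrix(design_2x4x3) -> ExpressionMatrix:
    """3 genes x 24 samples with constant within-group intensities."""
    rows = {
        # gene: (control, ifng, lps, combo) intensity per genotype (WT, KO)
        "g_synergy": ((10, 40, 40, 800), (10, 10, 20, 20)),
        "g_additive": ((10, 40, 40, 80), (10, 40, 40, 80)),
        "g_flat": ((10, 10, 10, 10), (10, 10, 10, 10)),
    }
    cond_order = [Condition.CONTROL, Condition.IFNG, Condition.LPS, Condition.COMBO]
    data = {}
    for s in design_2x4x3:
        geno_idx = 0 if s.genotype == Genotype.WT else 1
        ci = cond_order.index(s.condition)
        data[s.sample_id] = [rows[g][geno_idx][ci] for g in rows]
    values = pd.DataFrame(data, index=pd.Index(list(rows), name="gene_id"), dtype=float)
    detp = values * 0.0 + 0.001
    return ExpressionMatrix(values, detp)
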