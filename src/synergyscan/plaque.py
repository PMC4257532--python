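"""Cross-cohort gene-signature integration.

Collapses array probes to gene symbols, removes batch structure between
combined cohorts with a per-gene location–scale adjustment on the log2 scale,
applies the fold-change filter, maps mouse symbols onto human ones, intersects
signatures (Venn regions), and tests overlap enrichment with an exact
one-tailed hypergeometric test (optionally Benjamini–Hochberg corrected
across categories).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .preprocess import FoldChangeTable

__all__ = [
    "GeneSet",
    "VennCounts",
    "EnrichmentResult",
    "combine_probes_to_genes",
    "batch_adjust",
    "select_upregulated",
    "map_symbols",
    "intersect_gene_sets",
    "hypergeometric_enrichment",
    "bh_adjust",
    "load_alias_table",
    "read_gene_set",
]


@dataclass
class GeneSet:
    """A named set of upper-cased canonical gene symbols."""

    name: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, symbols) -> "GeneSet":
        return cls(name, frozenset(str(s).strip().upper() for s in symbols if str(s).strip()))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.members


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """One symbol per line; '#' comments and blank lines ignored."""
    path = Path(path)
    symbols = [
        line.strip()
        for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return GeneSet.from_iterable(name or path.stem, symbols)


@dataclass
class VennCounts:
    """Exclusive and shared region counts for 2–3 gene sets."""

    set_names: tuple[str, ...]
    regions: dict[frozenset[str], int]      # key: subset of set names
    members: dict[frozenset[str], frozenset[str]]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def count(self, *names: str) -> int:
        """Exact-region count: genes in exactly these sets and no others."""
        return self.regions[frozenset(names)]

    def intersection(self, *names: str) -> int:
        """Genes in all the named sets (regardless of membership elsewhere)."""
        want = frozenset(names)
        return sum(c for key, c in self.regions.items() if want <= key)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sorted(key)), "count": count,
             "members": ",".join(sorted(self.members[key]))}
            for key, count in sorted(self.regions.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    overlap: int
    p_value: float
    fold_enrichment: float
    hits: int
    category: int
    universe: int


def combine_probes_to_genes(
    m: ExpressionMatrix, probe2gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Average each gene's probes per sample; unmapped probes are dropped.

    A probe mapping to more than one symbol (separated by ``;`` ``,`` or
    ``/``) is rejected and reported.
    """
    if not probe2gene:
        raise ValueError("probe-to-gene mapping is empty")
    ambiguous = [
        p for p, g in probe2gene.items()
        if any(sep in str(g) for sep in ";,/")
    ]
    if ambiguous:
        raise ValueError(
            f"probe(s) mapping to multiple symbols rejected: {sorted(ambiguous)}"
        )
    mapped = [p for p in m.gene_ids if p in probe2gene]
    dropped = m.n_genes - len(mapped)
    if not mapped:
        raise ValueError("no probe in the matrix is covered by the mapping")
    values = m.values.loc[mapped]
    genes = pd.Series({p: str(probe2gene[p]) for p in mapped}, name="gene")
    collapsed = values.groupby(genes).mean()
    collapsed.index.name = m.values.index.name
    collapsed.attrs["n_probes_dropped"] = dropped
    return ExpressionMatrix(collapsed)


def batch_adjust(
    m: ExpressionMatrix, batches: Mapping[str, str]
) -> ExpressionMatrix:
    """Per-gene location–scale batch standardization on the log2 scale.

    Each batch's per-gene values are rescaled to the pooled gene mean and
    pooled standard deviation; for genes with zero variance inside a batch
    only the location shift is applied. A deliberate simplification of
    empirical-Bayes batch correction: no shrinkage across genes.
    """
    labels = pd.Series({s: batches[s] for s in m.sample_ids})
    groups = labels.groupby(labels).groups
    if len(groups) < 2:
        if len(groups) == 1:
            return m.copy()
        raise ValueError("no batch labels for the matrix samples")
    for batch, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"batch {batch!r} has fewer than 2 samples")
    X = np.log2(m.values.to_numpy(dtype=float))
    out = np.empty_like(X)
    pooled_mean = X.mean(axis=1)
    pooled_sd = X.std(axis=1, ddof=1)
    col_index = {s: j for j, s in enumerate(m.sample_ids)}
    for samples in groups.values():
        cols = [col_index[s] for s in samples]
        block = X[:, cols]
        b_mean = block.mean(axis=1)
        b_sd = block.std(axis=1, ddof=1)
        scale = np.where(b_sd > 0, pooled_sd / np.where(b_sd > 0, b_sd, 1.0), 1.0)
        adjusted = (block - b_mean[:, None]) * scale[:, None] + pooled_mean[:, None]
        out[:, cols] = adjusted
    values = pd.DataFrame(
        2.0 ** out, index=m.values.index, columns=m.values.columns
    )
    return ExpressionMatrix(values, m.detection_p)


def select_upregulated(
    fc: FoldChangeTable | pd.DataFrame,
    min_fold: float = 1.5,
    condition: str | None = None,
    name: str = "upregulated",
) -> GeneSet:
    """Symbols whose fold change is at least ``min_fold`` (inclusive).

    For a multi-condition fold table, ``condition`` picks the column
    (default: any condition passing).
    """
    data = fc.data if isinstance(fc, FoldChangeTable) else fc
    fold_cols = [c for c in data.columns if c.endswith("_fold")]
    if condition is not None:
        fold_cols = [f"{condition}_fold"]
    if not fold_cols or any(c not in data.columns for c in fold_cols):
        raise ValueError(f"fold column(s) not found: {fold_cols}")
    passing = (data[fold_cols] >= min_fold).any(axis=1)
    return GeneSet.from_iterable(name, data.index[passing])


def load_alias_table() -> dict[str, str]:
    """Packaged legacy-name aliases (e.g. MCP-5 → CCL12)."""
    text = (
        resources.files("synergyscan").joinpath("data/gene_aliases.tsv").read_text()
    )
    aliases: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if line.strip():
            alias, symbol = line.split("\t")
            aliases[alias.strip().upper()] = symbol.strip().upper()
    return aliases


def map_symbols(
    genes: GeneSet,
    mode: str = "uppercase",
    table: Mapping[str, str] | None = None,
    aliases: Mapping[str, str] | None = None,
) -> GeneSet:
    """Map symbols across species for comparison.

    ``uppercase`` case-folds mouse-style symbols (Cxcl9 → CXCL9); ``table``
    uses a user-supplied ortholog mapping. The packaged legacy-alias list
    (or one passed in) is applied first in either mode.
    """
    if mode not in ("uppercase", "table"):
        raise ValueError(f"unknown mapping mode {mode!r}")
    if mode == "table" and table is None:
        raise ValueError("table mode requires an ortholog table")
    alias_map = {k.upper(): v.upper() for k, v in (aliases or load_alias_table()).items()}
    mapped = []
    for symbol in genes.members:
        symbol = alias_map.get(symbol.upper(), symbol.upper())
        if mode == "table":
            upper_table = {k.upper(): str(v).upper() for k, v in table.items()}
            if symbol not in upper_table:
                continue
            symbol = upper_table[symbol]
        mapped.append(symbol)
    return GeneSet.from_iterable(genes.name, mapped)


def intersect_gene_sets(sets: list[GeneSet]) -> VennCounts:
    """Exclusive Venn region counts and member lists for 2–3 sets."""
    if not 2 <= len(sets) <= 3:
        raise ValueError("intersect_gene_sets supports 2 or 3 sets")
    names = tuple(s.name for s in sets)
    if len(set(names)) != len(names):
        raise ValueError("gene sets must have distinct names")
    union = frozenset().union(*(s.members for s in sets))
    regions: dict[frozenset[str], int] = {}
    members: dict[frozenset[str], frozenset[str]] = {}
    from itertools import combinations

    for r in range(1, len(sets) + 1):
        for combo in combinations(sets, r):
            key = frozenset(s.name for s in combo)
            inside = frozenset.intersection(*(s.members for s in combo))
            outside = frozenset().union(
                *(s.members for s in sets if s.name not in key)
            ) if r < len(sets) else frozenset()
            exclusive = inside - outside
            regions[key] = len(exclusive)
            members[key] = exclusive
    counts = VennCounts(names, regions, members)
    assert counts.union_size == len(union)
    return counts


def hypergeometric_enrichment(
    hits: GeneSet, category: GeneSet, universe: GeneSet
) -> EnrichmentResult:
    """Exact upper-tail overlap test: P(X >= observed) under random draws.

    ``hits`` are the genes selected by the analysis, ``category`` the
    annotation set; both must lie inside ``universe``. Fold enrichment is the
    observed overlap fraction over its expectation.
    """
    if len(universe) == 0:
        raise ValueError("universe is empty")
    if not hits.members <= universe.members:
        raise ValueError("hits must be a subset of the universe")
    if not category.members <= universe.members:
        raise ValueError("category must be a subset of the universe")
    N, K, n = len(universe), len(category), len(hits)
    k = len(hits.members & category.members)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
    if n == 0 or K == 0:
        fold = float("nan")
    else:
        fold = (k / n) / (K / N)
    return EnrichmentResult(
        overlap=k, p_value=min(p, 1.0), fold_enrichment=fold,
        hits=n, category=K, universe=N,
    )


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values across a family of categories."""
    if not p_values:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])
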