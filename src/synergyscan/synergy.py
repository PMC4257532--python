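"""The signal-integration statistic and gene classifications.

Two stimuli (IFNγ and LPS) acting through independent pathways would at most
add their single-treatment fold inductions. The signal-integration ratio

    si = fold(IFNγ+LPS) / (fold(IFNγ) + fold(LPS))

measures departure from that additive expectation: si ≥ 2 defines a
synergistically *amplified* gene. Genes are further classified by their
dependence on STAT1 (comparing wild-type with STAT1-null fold inductions) and
by their single-agent response pattern into five qualitative clusters:

    A — high response to both IFNγ and LPS
    B — high IFNγ, mild LPS
    C — mild/no IFNγ, high LPS
    D — mild response to both
    E — minor/no single-agent response, amplified only in combination
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .io import Genotype
from .preprocess import FoldChangeTable

__all__ = [
    "Stat1Dependence",
    "Cluster",
    "SynergyThresholds",
    "SynergyRecord",
    "SynergyTable",
    "signal_integration",
    "call_upregulated",
    "call_amplified",
    "classify_stat1_dependence",
    "assign_cluster",
    "build_synergy_table",
]


class Stat1Dependence(str, enum.Enum):
    DEPENDENT = "dependent"
    INDEPENDENT = "independent"
    NOT_ASSESSABLE = "not_assessable"


class Cluster(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class SynergyThresholds:
    """All cut-offs used by the callers; every one is inclusive where stated.

    ``min_fold_up``/``alpha`` define up-regulation (≥2-fold, p<0.05);
    ``min_si`` the amplification call on the unrounded ratio; ``ko_reduction``
    and ``ko_min_fold`` the STAT1-dependence rule (knockout fold reduced to
    ≤50% of wild type, or below 2-fold induction). ``ifng_high``, ``lps_high``
    and ``response_floor`` parameterize the qualitative A–E cluster tree; the
    source analysis describes the clusters only as "high"/"mild", so these
    numeric defaults are this package's own calibration and fully
    configurable.
    """

    min_fold_up: float = 2.0
    alpha: float = 0.05
    min_si: float = 2.0
    ko_reduction: float = 0.5
    ko_min_fold: float = 2.0
    ifng_high: float = 20.0
    lps_high: float = 15.0
    response_floor: float = 2.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"threshold {name} must be strictly positive")
        if not (0 < self.ko_reduction < 1):
            raise ValueError("ko_reduction must be in (0, 1)")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class SynergyRecord:
    gene_id: str
    fc_wt_ifng: float
    fc_wt_lps: float
    fc_wt_combo: float
    fc_ko_ifng: float
    fc_ko_lps: float
    fc_ko_combo: float
    si: float
    upregulated_combo: bool
    amplified: bool
    stat1_dependent_ifng: Stat1Dependence
    stat1_dependent_lps: Stat1Dependence
    stat1_dependent_combo: Stat1Dependence
    cluster: Cluster


def signal_integration(fc_combo: float, fc_ifng: float, fc_lps: float) -> float:
    """Combined-treatment fold change over the sum of the single-agent folds."""
    denominator = fc_ifng + fc_lps
    if denominator <= 0:
        raise ValueError(
            f"sum of single-treatment folds must be positive, got {denominator}"
        )
    return fc_combo / denominator


def call_upregulated(
    fold: float, p: float | None, th: SynergyThresholds | None = None
) -> bool:
    """Significant up-regulation: fold ≥ min_fold_up (inclusive) and p < alpha."""
    th = th or SynergyThresholds()
    if p is None or (isinstance(p, float) and np.isnan(p)):
        warnings.warn("missing p-value treated as not significant")
        return False
    return fold >= th.min_fold_up and p < th.alpha


def call_amplified(rec: SynergyRecord, th: SynergyThresholds | None = None) -> bool:
    """Amplified: combo-upregulated and unrounded si ≥ min_si (inclusive)."""
    th = th or SynergyThresholds()
    return bool(rec.upregulated_combo and rec.si >= th.min_si)


def classify_stat1_dependence(
    fc_wt: float,
    fc_ko: float,
    th: SynergyThresholds | None = None,
    wt_regulated: bool = True,
) -> Stat1Dependence:
    """STAT1 dependence of one condition's response.

    Assessable only for genes regulated in wild type; dependent when the
    knockout fold drops to ≤ ko_reduction of the wild-type fold (inclusive)
    or falls below ko_min_fold induction.
    """
    th = th or SynergyThresholds()
    if fc_wt <= 0 or fc_ko <= 0:
        raise ValueError("fold changes must be strictly positive")
    if not wt_regulated:
        return Stat1Dependence.NOT_ASSESSABLE
    if fc_ko <= th.ko_reduction * fc_wt or fc_ko < th.ko_min_fold:
        return Stat1Dependence.DEPENDENT
    return Stat1Dependence.INDEPENDENT


def assign_cluster(
    fc_ifng: float, fc_lps: float, th: SynergyThresholds | None = None
) -> Cluster:
    """Qualitative A–E response class from the two single-agent folds.

    Decision tree, first match wins:
      1. LPS fold below the response floor → E (no real LPS response; the
         minor-response class takes precedence even for genes with some IFNγ
         response);
      2. both folds high → A;
      3. IFNγ high → B;
      4. LPS high → C;
      5. otherwise → D (mild response to both).
    """
    th = th or SynergyThresholds()
    if fc_ifng <= 0 or fc_lps <= 0:
        raise ValueError("fold changes must be strictly positive")
    if fc_lps < th.response_floor:
        return Cluster.E
    if fc_ifng >= th.ifng_high and fc_lps >= th.lps_high:
        return Cluster.A
    if fc_ifng >= th.ifng_high:
        return Cluster.B
    if fc_lps >= th.lps_high:
        return Cluster.C
    return Cluster.D


_CLUSTER_ORDER = {c: i for i, c in enumerate("ABCDE")}


@dataclass
class SynergyTable:
    """Ordered collection of SynergyRecords plus the thresholds that made them."""

    records: list[SynergyRecord]
    thresholds: SynergyThresholds

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, gene_id: str) -> SynergyRecord:
        for rec in self.records:
            if rec.gene_id == gene_id:
                return rec
        raise KeyError(gene_id)

    def top(self, n: int) -> "SynergyTable":
        return SynergyTable(self.records[:n], self.thresholds)

    def amplified(self) -> list[SynergyRecord]:
        return [r for r in self.records if r.amplified]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = asdict(r)
            for key in (
                "stat1_dependent_ifng",
                "stat1_dependent_lps",
                "stat1_dependent_combo",
            ):
                d[key] = d[key].value
            d["cluster"] = d["cluster"].value
            rows.append(d)
        return pd.DataFrame(rows).set_index("gene_id")

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", lineterminator="\n")


def build_synergy_table(
    fc_wt: FoldChangeTable,
    fc_ko: FoldChangeTable,
    th: SynergyThresholds | None = None,
    missing_p: str = "not_significant",
    top_n: int | None = None,
) -> SynergyTable:
    """Assemble per-gene synergy records from wild-type and knockout fold tables.

    One record per gene shared by both tables, sorted by cluster (A..E) then
    descending combined-treatment fold, gene id breaking ties. ``missing_p``
    controls how absent p-values are treated for the up-regulation call:
    ``'not_significant'`` (default) or ``'significant'`` (for fold-only inputs
    such as published tables).
    """
    th = th or SynergyThresholds()
    if missing_p not in ("not_significant", "significant"):
        raise ValueError(f"unknown missing_p policy {missing_p!r}")
    if fc_wt.genotype != Genotype.WT or fc_ko.genotype != Genotype.KO:
        raise ValueError("build_synergy_table expects a WT and a KO fold table")
    shared = [g for g in fc_wt.gene_ids if g in set(fc_ko.gene_ids)]
    if not shared:
        raise ValueError("wild-type and knockout fold tables share no genes")

    def _p(table: FoldChangeTable, gene: str, cond: str) -> float | None:
        col = f"{cond}_p"
        if col not in table.data.columns:
            return None
        v = table.data.at[gene, col]
        return None if pd.isna(v) else float(v)

    records = []
    with warnings.catch_warnings():
        if missing_p == "significant":
            warnings.simplefilter("ignore")
        for gene in shared:
            wt = {c: fc_wt.fold(gene, c) for c in ("ifng", "lps", "combo")}
            ko = {c: fc_ko.fold(gene, c) for c in ("ifng", "lps", "combo")}
            si = signal_integration(wt["combo"], wt["ifng"], wt["lps"])
            up = {}
            for cond in ("ifng", "lps", "combo"):
                p = _p(fc_wt, gene, cond)
                if p is None and missing_p == "significant":
                    up[cond] = wt[cond] >= th.min_fold_up
                else:
                    up[cond] = call_upregulated(wt[cond], p, th)
            dep = {
                cond: classify_stat1_dependence(
                    wt[cond], ko[cond], th, wt_regulated=up[cond]
                )
                for cond in ("ifng", "lps", "combo")
            }
            rec = SynergyRecord(
                gene_id=gene,
                fc_wt_ifng=wt["ifng"],
                fc_wt_lps=wt["lps"],
                fc_wt_combo=wt["combo"],
                fc_ko_ifng=ko["ifng"],
                fc_ko_lps=ko["lps"],
                fc_ko_combo=ko["combo"],
                si=si,
                upregulated_combo=up["combo"],
                amplified=False,
                stat1_dependent_ifng=dep["ifng"],
                stat1_dependent_lps=dep["lps"],
                stat1_dependent_combo=dep["combo"],
                cluster=assign_cluster(wt["ifng"], wt["lps"], th),
            )
            rec.amplified = call_amplified(rec, th)
            records.append(rec)

    records.sort(
        key=lambda r: (
            _CLUSTER_ORDER.get(r.cluster.value, len(_CLUSTER_ORDER)),
            -r.fc_wt_combo,
            r.gene_id,
        )
    )
    table = SynergyTable(records, th)
    return table.top(top_n) if top_n is not None else table
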