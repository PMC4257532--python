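"""Synthetic inputs with the statistical structure the analysis assumes.

The expression simulator draws log2 intensities from a two-factor linear
model with an interaction term,

    log2 x = mu + beta_I * I + beta_L * L + gamma * I * L + eps,
    eps ~ Normal(0, sigma^2),

over a WT / STAT1-knockout x control / IFNγ / LPS / combined design with
replicates. In knockout samples the IFNγ effect and the interaction are
ablated for STAT1-dependent genes and the LPS effect is attenuated by a
dependence factor rho. A gene is *designed-amplified* when its noiseless
linear folds satisfy the synergy rule, i.e.

    2^(beta_I + beta_L + gamma) >= 2 * (2^beta_I + 2^beta_L).

The promoter simulator writes i.i.d.-background sequences with consensus
sites planted at recorded positions and strands. Everything is driven by a
single seed and is byte-reproducible.

Also packaged here: the 30-gene published fold-change table used as a
desk-checkable fixture (checksummed on load).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .io import (
    Condition,
    ConditionDesign,
    ExpressionMatrix,
    Genotype,
    PromoterSet,
    SampleInfo,
)
from .motifs import DEFAULT_CLASS_CONSENSUS, TFClass, reverse_complement
from .preprocess import FoldChangeTable
from .synergy import assign_cluster

__all__ = [
    "SimulationTruth",
    "PlantSpec",
    "PlantedSite",
    "simulate_expression",
    "simulate_promoters",
    "Table1Fixture",
    "load_table1_fixture",
]

_TABLE1_SHA256 = "09e1cc753a7a61034c8d4690309ec3667aeef887895750dfb6ba042084e4c498"


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run: per-gene design and/or planted sites."""

    genes: pd.DataFrame | None = None
    planted_sites: list["PlantedSite"] = field(default_factory=list)
    seed: int | None = None

    def designed_amplified(self) -> list[str]:
        if self.genes is None:
            return []
        return list(self.genes.index[self.genes["designed_amplified"]])


def simulate_expression(
    n_genes: int = 2000,
    frac_amplified: float = 0.10,
    frac_stat1_dependent: float = 0.5,
    frac_undetected: float = 0.05,
    baseline_range: tuple[float, float] = (6.0, 12.0),
    amplified_effect_range: tuple[float, float] = (0.5, 4.0),
    additive_effect_range: tuple[float, float] = (0.0, 1.5),
    gamma_margin_range: tuple[float, float] = (1.0, 2.0),
    rho: float = 0.5,
    sigma_log2: float = 0.25,
    n_reps: int = 3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ConditionDesign, SimulationTruth]:
    """Simulate a WT/KO x 4-condition expression experiment with known truth.

    ``frac_amplified`` of genes receive an interaction term gamma large enough
    that their designed folds pass the synergy rule with margin
    ``gamma_margin_range`` (log2); the rest combine additively in log2
    (gamma = 0) with main effects capped by ``additive_effect_range`` so their
    designed signal-integration ratio stays below 2. ``frac_undetected`` genes
    are expressed near background with uniform detection p-values; all others
    get detection p-values near 0. ``rho`` attenuates the LPS effect in the
    knockout for STAT1-dependent genes.
    """
    for name, frac in (
        ("frac_amplified", frac_amplified),
        ("frac_stat1_dependent", frac_stat1_dependent),
        ("frac_undetected", frac_undetected),
    ):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")
    rng = np.random.default_rng(seed)

    n_amp = int(round(frac_amplified * n_genes))
    amplified = np.zeros(n_genes, dtype=bool)
    amplified[rng.choice(n_genes, size=n_amp, replace=False)] = True
    undetected = rng.random(n_genes) < frac_undetected
    stat1_dep = rng.random(n_genes) < frac_stat1_dependent

    mu = rng.uniform(*baseline_range, size=n_genes)
    mu[undetected] = baseline_range[0] - 2.0  # near background

    beta_i = np.where(
        amplified,
        rng.uniform(*amplified_effect_range, size=n_genes),
        rng.uniform(*additive_effect_range, size=n_genes),
    )
    beta_l = np.where(
        amplified,
        rng.uniform(*amplified_effect_range, size=n_genes),
        rng.uniform(*additive_effect_range, size=n_genes),
    )
    # smallest gamma meeting the synergy rule with equality, plus a margin
    gamma_min = np.log2(2.0 * (2.0 ** beta_i + 2.0 ** beta_l)) - beta_i - beta_l
    gamma = np.where(
        amplified,
        gamma_min + rng.uniform(*gamma_margin_range, size=n_genes),
        0.0,
    )
    beta_i[undetected] = beta_l[undetected] = 0.0
    gamma[undetected] = 0.0
    amplified &= ~undetected

    designed_amp = 2.0 ** (beta_i + beta_l + gamma) >= 2.0 * (
        2.0 ** beta_i + 2.0 ** beta_l
    )

    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    samples: list[SampleInfo] = []
    columns: dict[str, np.ndarray] = {}
    detp: dict[str, np.ndarray] = {}
    for genotype in (Genotype.WT, Genotype.KO):
        ko = genotype == Genotype.KO
        bi = np.where(ko & stat1_dep, 0.0, beta_i) if ko else beta_i
        bl = np.where(ko & stat1_dep, rho * beta_l, beta_l) if ko else beta_l
        g = np.where(ko & stat1_dep, 0.0, gamma) if ko else gamma
        for condition in Condition:
            has_i = condition in (Condition.IFNG, Condition.COMBO)
            has_l = condition in (Condition.LPS, Condition.COMBO)
            expected = mu + bi * has_i + bl * has_l + g * (has_i and has_l)
            for rep in range(1, n_reps + 1):
                sid = f"{genotype.value}_{condition.value}_{rep}"
                noise = rng.normal(0.0, sigma_log2, size=n_genes)
                columns[sid] = 2.0 ** (expected + noise)
                p = rng.uniform(0.0, 0.01, size=n_genes)
                p[undetected] = rng.uniform(0.0, 1.0, size=int(undetected.sum()))
                detp[sid] = p
                samples.append(SampleInfo(sid, genotype, condition, rep))

    index = pd.Index(gene_ids, name="gene_id")
    matrix = ExpressionMatrix(
        pd.DataFrame(columns, index=index),
        pd.DataFrame(detp, index=index),
    )
    design = ConditionDesign(samples)
    truth_genes = pd.DataFrame(
        {
            "mu": mu,
            "beta_i": beta_i,
            "beta_l": beta_l,
            "gamma": gamma,
            "stat1_dependent": stat1_dep,
            "expressed": ~undetected,
            "designed_amplified": designed_amp,
            "cluster_design": [
                assign_cluster(2.0 ** bi_, 2.0 ** bl_).value
                for bi_, bl_ in zip(beta_i, beta_l)
            ],
        },
        index=index,
    )
    return matrix, design, SimulationTruth(genes=truth_genes, seed=seed)


@dataclass(frozen=True)
class PlantSpec:
    """One site to plant in every simulated promoter.

    ``position`` is the TSS-relative start of the site (None = random per
    promoter); ``strand`` '+' or '-' (None = random).
    """

    tf_class: TFClass
    consensus: str | None = None
    position: int | None = None
    strand: str | None = None

    def sequence(self) -> str:
        if self.consensus is not None:
            return self.consensus.upper()
        return DEFAULT_CLASS_CONSENSUS[self.tf_class.value]


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    tf_class: TFClass
    start: int  # TSS-relative, half-open, + strand
    end: int
    strand: str
    mutated: bool


def simulate_promoters(
    n: int,
    length: int = 1100,
    planted: list[PlantSpec] | None = None,
    mutation_rate: float = 0.0,
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    window: tuple[int, int] | None = None,
    seed: int = 0,
    allow_overlap: bool = False,
) -> tuple[PromoterSet, SimulationTruth]:
    """Simulate promoter windows with known planted binding sites.

    Background bases are i.i.d. with ``base_probs`` (order A, C, G, T). Each
    ``PlantSpec`` is written into every promoter at its requested or a random
    non-overlapping position. ``mutation_rate`` is the per-site probability
    that a planted occurrence carries a single random point substitution —
    modelling the site-to-site sequence divergence that matrix building must
    tolerate while leaving most occurrences exact.
    """
    if window is None:
        window = (-length + 100, 100) if length > 100 else (0, length)
    w_start, w_end = window
    if w_end - w_start != length:
        raise ValueError("window span must equal promoter length")
    if not 0 <= mutation_rate <= 1:
        raise ValueError("mutation_rate must be in [0, 1]")
    planted = planted or []
    for spec in planted:
        if len(spec.sequence()) > length:
            raise ValueError("planted site longer than promoter")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    sites: list[PlantedSite] = []
    for i in range(n):
        gene = f"prom{i:04d}"
        seq = rng.choice(bases, size=length, p=base_probs)
        occupied: list[tuple[int, int]] = []
        for spec in planted:
            site_seq = spec.sequence()
            L = len(site_seq)
            strand = spec.strand or ("+" if rng.random() < 0.5 else "-")
            if spec.position is not None:
                pos = spec.position - w_start
                if not 0 <= pos <= length - L:
                    raise ValueError(
                        f"planted position {spec.position} outside window {window}"
                    )
            else:
                for _ in range(200):
                    pos = int(rng.integers(0, length - L + 1))
                    if allow_overlap or all(
                        pos + L <= s or pos >= e for s, e in occupied
                    ):
                        break
                else:
                    raise ValueError("could not place site without overlap")
            if not allow_overlap and any(
                pos < e and pos + L > s for s, e in occupied
            ):
                raise ValueError(
                    f"planted sites overlap at promoter {gene}; "
                    "pass allow_overlap=True to permit this"
                )
            occupied.append((pos, pos + L))
            written = site_seq if strand == "+" else reverse_complement(site_seq)
            written = np.array(list(written))
            mutated = rng.random() < mutation_rate
            if mutated:
                j = int(rng.integers(0, L))
                written[j] = rng.choice([b for b in "ACGT" if b != written[j]])
            seq[pos : pos + L] = written
            sites.append(
                PlantedSite(
                    gene_id=gene,
                    tf_class=spec.tf_class,
                    start=w_start + pos,
                    end=w_start + pos + L,
                    strand=strand,
                    mutated=mutated,
                )
            )
        sequences[gene] = "".join(seq)
    proms = PromoterSet(sequences, window_start=w_start, window_end=w_end)
    return proms, SimulationTruth(planted_sites=sites, seed=seed)


@dataclass
class Table1Fixture:
    """The packaged 30-gene published fold-change table.

    ``frame`` holds, per gene: WT and STAT1-knockout fold changes for the
    IFNγ, LPS and combined treatments; the printed signal-integration ratio;
    printed promoter site-presence marks; and the printed cluster label.
    """

    frame: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    def printed_si(self, gene: str) -> float:
        return float(self.frame.at[gene, "signal_integration"])

    def printed_cluster(self, gene: str) -> str:
        return str(self.frame.at[gene, "cluster"])

    def fold_tables(self) -> tuple[FoldChangeTable, FoldChangeTable]:
        """WT and knockout fold tables (folds only, no p-values)."""
        wt = pd.DataFrame(
            {
                "ifng_fold": self.frame["wt_ifng"],
                "lps_fold": self.frame["wt_lps"],
                "combo_fold": self.frame["wt_combo"],
            }
        )
        ko = pd.DataFrame(
            {
                "ifng_fold": self.frame["ko_ifng"],
                "lps_fold": self.frame["ko_lps"],
                "combo_fold": self.frame["ko_combo"],
            }
        )
        return FoldChangeTable(Genotype.WT, wt), FoldChangeTable(Genotype.KO, ko)

    def site_presence(self) -> pd.DataFrame:
        """Printed promoter annotation marks as booleans ('x'/'X' = present)."""
        cols = {"stat_nfkb": "STAT_NFKB", "irf_nfkb": "IRF_NFKB",
                "isre": "ISRE", "stat": "STAT", "nfkb": "NFKB"}
        out = pd.DataFrame(index=self.frame.index)
        for src, dst in cols.items():
            out[dst] = self.frame[src].str.lower().eq("x")
        return out


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged published table, verifying its checksum."""
    data = (
        resources.files("synergyscan").joinpath("data/table1.tsv").read_bytes()
    )
    digest = hashlib.sha256(data).hexdigest()
    if digest != _TABLE1_SHA256:
        raise RuntimeError(
            "packaged fixture table1.tsv failed its integrity check: "
            f"sha256 {digest} != {_TABLE1_SHA256}"
        )
    from io import BytesIO

    frame = pd.read_csv(BytesIO(data), sep="\t", index_col="symbol", dtype={
        "stat_nfkb": str, "irf_nfkb": str, "isre": str, "stat": str,
        "nfkb": str, "cluster": str,
    })
    return Table1Fixture(frame)
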