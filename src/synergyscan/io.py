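"""Readers and core containers for expression matrices, designs, and promoters.

The tabular formats follow GEO conventions: tab-delimited matrices with gene
identifiers in the first column and sample identifiers in the header. Per-probe
detection p-values (the BeadChip statistic for signal vs. background) travel in
the same file as ``<sample>.detp`` columns. Promoter sequences come from FASTA
with coordinates expressed relative to the transcription start site (TSS at 0,
upstream negative, half-open windows).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Genotype",
    "Condition",
    "ExpressionMatrix",
    "ConditionDesign",
    "PromoterSet",
    "FormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "write_design",
    "read_promoters",
    "write_promoters",
]

DETECTION_SUFFIX = ".detp"


class FormatError(ValueError):
    """An input file violates the structural contract of its format."""


class Genotype(str, enum.Enum):
    WT = "WT"
    KO = "KO"


class Condition(str, enum.Enum):
    CONTROL = "CONTROL"
    IFNG = "IFNG"
    LPS = "LPS"
    COMBO = "COMBO"


#: accepted spellings for design-file condition values (case-insensitive)
_CONDITION_ALIASES = {
    "CONTROL": Condition.CONTROL,
    "CTRL": Condition.CONTROL,
    "UNTREATED": Condition.CONTROL,
    "IFNG": Condition.IFNG,
    "IFN": Condition.IFNG,
    "IFNGAMMA": Condition.IFNG,
    "LPS": Condition.LPS,
    "COMBO": Condition.COMBO,
    "IFNG+LPS": Condition.COMBO,
    "IFNG_LPS": Condition.COMBO,
}

_GENOTYPE_ALIASES = {
    "WT": Genotype.WT,
    "KO": Genotype.KO,
    "STAT1KO": Genotype.KO,
    "STAT1-/-": Genotype.KO,
}


@dataclass
class ExpressionMatrix:
    """Genes x samples of linear-scale intensities, with optional detection p.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    ``detection_p``, when present, shares both axes exactly.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene id(s): {', '.join(map(str, dupes))}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(f"duplicate sample id(s): {', '.join(map(str, dupes))}")
        if self.detection_p is not None:
            if not self.detection_p.index.equals(self.values.index) or not (
                self.detection_p.columns.equals(self.values.columns)
            ):
                raise FormatError("detection_p axes do not match values axes")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        idx = [g for g in self.gene_ids if g in set(gene_ids)]
        detp = self.detection_p.loc[idx] if self.detection_p is not None else None
        return ExpressionMatrix(self.values.loc[idx], detp)

    def copy(self) -> "ExpressionMatrix":
        detp = None if self.detection_p is None else self.detection_p.copy()
        return ExpressionMatrix(self.values.copy(), detp)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        if not self.values.equals(other.values):
            return False
        if (self.detection_p is None) != (other.detection_p is None):
            return False
        return self.detection_p is None or self.detection_p.equals(other.detection_p)


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    genotype: Genotype
    condition: Condition
    replicate: int


@dataclass
class ConditionDesign:
    """Maps each sample to its (genotype, condition, replicate) cell."""

    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dupes: list[str] = []
        for s in self.samples:
            if s.sample_id in seen:
                dupes.append(s.sample_id)
            seen.add(s.sample_id)
        if dupes:
            raise FormatError(f"duplicate sample id(s) in design: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def group(self, genotype: Genotype, condition: Condition) -> list[str]:
        """Sample ids in one (genotype, condition) cell, design order."""
        return [
            s.sample_id
            for s in self.samples
            if s.genotype == genotype and s.condition == condition
        ]

    def genotypes(self) -> list[Genotype]:
        seen: list[Genotype] = []
        for s in self.samples:
            if s.genotype not in seen:
                seen.append(s.genotype)
        return seen

    def treated_samples(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.condition != Condition.CONTROL]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "genotype": [s.genotype.value for s in self.samples],
                "condition": [s.condition.value for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )


@dataclass
class PromoterSet:
    """TSS-relative promoter windows: half-open [window_start, window_end), 0 = TSS."""

    sequences: dict[str, str]
    window_start: int = -1000
    window_end: int = 100

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise FormatError(
                    f"promoter {gene}: invalid character(s) {sorted(bad)}"
                )

    @property
    def window(self) -> tuple[int, int]:
        return (self.window_start, self.window_end)

    @property
    def length(self) -> int:
        return self.window_end - self.window_start

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences.items())


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a gene x sample intensity matrix.

    The first column holds gene ids; any column named ``<sample>.detp`` is
    split off into the detection p-value grid for that sample.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dupes = raw.index[raw.index.duplicated()].unique()
        raise FormatError(f"duplicate gene id(s): {', '.join(map(str, dupes))}")

    detp_cols = [c for c in raw.columns if c.endswith(DETECTION_SUFFIX)]
    value_cols = [c for c in raw.columns if c not in detp_cols]

    def _numeric(frame: pd.DataFrame, what: str) -> pd.DataFrame:
        out = frame.apply(pd.to_numeric, errors="coerce")
        if out.isna().values.any() and frame.notna().values.any():
            bad = out.isna() & frame.notna()
            rows, cols = np.nonzero(bad.values)
            g, s = frame.index[rows[0]], frame.columns[cols[0]]
            raise FormatError(
                f"non-numeric {what} cell at gene {g!r}, column {s!r}: "
                f"{frame.at[g, s]!r}"
            )
        return out.astype(float)

    values = _numeric(raw[value_cols], "intensity")
    detection_p = None
    if detp_cols:
        detp = _numeric(raw[detp_cols], "detection p-value")
        detp.columns = [c[: -len(DETECTION_SUFFIX)] for c in detp_cols]
        missing = [c for c in values.columns if c not in detp.columns]
        if missing:
            raise FormatError(
                f"detection columns present but missing for sample(s): {missing}"
            )
        detection_p = detp[values.columns]
    return ExpressionMatrix(values, detection_p)


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    out = m.values.copy()
    if m.detection_p is not None:
        for c in m.detection_p.columns:
            out[c + DETECTION_SUFFIX] = m.detection_p[c]
    out.index.name = "gene_id"
    out.to_csv(path, sep=sep, lineterminator="\n")


def _parse_enum(value: str, table: Mapping[str, object], what: str):
    key = str(value).strip().upper()
    if key not in table:
        raise FormatError(
            f"unknown {what} {value!r}; allowed: {sorted(set(table))}"
        )
    return table[key]


def read_design(path: str | Path) -> ConditionDesign:
    """Read a sample design table (columns sample_id, genotype, condition, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"design file missing column(s): {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        try:
            rep = int(row["replicate"])
        except ValueError as exc:
            raise FormatError(
                f"replicate must be an integer, got {row['replicate']!r}"
            ) from exc
        if rep < 1:
            raise FormatError(f"replicate must be positive, got {rep}")
        samples.append(
            SampleInfo(
                sample_id=str(row["sample_id"]),
                genotype=_parse_enum(row["genotype"], _GENOTYPE_ALIASES, "genotype"),
                condition=_parse_enum(row["condition"], _CONDITION_ALIASES, "condition"),
                replicate=rep,
            )
        )
    return ConditionDesign(samples)


def write_design(design: ConditionDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_promoters(
    path: str | Path,
    window: tuple[int, int] = (-1000, 100),
    strict: bool = True,
) -> PromoterSet:
    """Read promoter FASTA; the gene id is the first token of each header.

    In strict mode every sequence must span the full window.
    """
    start, end = window
    expected = end - start
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        gene = record.id.split()[0]
        if gene in sequences:
            raise FormatError(f"duplicate promoter record for {gene!r}")
        seq = str(record.seq).upper()
        if strict and len(seq) != expected:
            raise FormatError(
                f"promoter {gene}: length {len(seq)} != window span {expected}"
            )
        sequences[gene] = seq
    return PromoterSet(sequences, window_start=start, window_end=end)


def write_promoters(proms: PromoterSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene, seq in proms:
            fh.write(f">{gene} window={proms.window_start}:{proms.window_end}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
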