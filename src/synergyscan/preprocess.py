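"""Intensity preprocessing and fold-change estimation.

Covers the microarray path (detection filtering, background subtraction,
quantile normalization, per-condition fold changes with a Welch test on log2
values) and the two qPCR quantification formulas: relative expression by
2^-ddCt and ChIP enrichment as a fraction of input chromatin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import Condition, ConditionDesign, ExpressionMatrix, Genotype

__all__ = [
    "FoldChangeTable",
    "CtTable",
    "filter_detected",
    "background_subtract",
    "quantile_normalize",
    "condition_fold_changes",
    "ddct",
    "percent_input",
]

#: canonical per-genotype fold-table columns
FOLD_COLUMNS = [
    "ifng_fold",
    "ifng_p",
    "lps_fold",
    "lps_p",
    "combo_fold",
    "combo_p",
]

_COND_KEY = {
    Condition.IFNG: "ifng",
    Condition.LPS: "lps",
    Condition.COMBO: "combo",
}


@dataclass
class FoldChangeTable:
    """Per-gene linear fold changes vs. control for one genotype.

    ``data`` is indexed by gene id with columns ``{ifng,lps,combo}_fold`` and
    ``_p``; fold changes are linear ratios of replicate means, p-values come
    from a two-sided Welch test on log2 intensities (NaN when a group has a
    single replicate). Down-regulation is a fold below 1, never sign-flipped.
    """

    genotype: Genotype
    data: pd.DataFrame

    def __post_init__(self) -> None:
        fold_cols = [c for c in self.data.columns if c.endswith("_fold")]
        if not fold_cols:
            raise ValueError("fold table has no *_fold columns")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene ids in fold table")
        folds = self.data[fold_cols].to_numpy(dtype=float)
        if np.any(folds[np.isfinite(folds)] <= 0):
            raise ValueError("fold changes must be strictly positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def fold(self, gene: str, condition: str) -> float:
        return float(self.data.at[gene, f"{condition}_fold"])

    def pvalue(self, gene: str, condition: str) -> float:
        return float(self.data.at[gene, f"{condition}_p"])

    def write(self, path) -> None:
        out = self.data.copy()
        out.columns = [f"{self.genotype.value}_{c}" for c in out.columns]
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", lineterminator="\n")


@dataclass
class CtTable:
    """qPCR cycle thresholds: one target and one reference Ct per sample."""

    data: pd.DataFrame  # columns: sample_id, target_ct, reference_ct, group

    def __post_init__(self) -> None:
        required = {"sample_id", "target_ct", "reference_ct", "group"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
        if self.data["reference_ct"].isna().any():
            bad = self.data.loc[self.data["reference_ct"].isna(), "sample_id"]
            raise ValueError(
                f"missing reference Ct for sample(s): {', '.join(map(str, bad))}"
            )

    @classmethod
    def read(cls, path) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"))


def filter_detected(
    m: ExpressionMatrix,
    design: ConditionDesign,
    alpha: float = 0.05,
    scope: str = "any_treated",
) -> ExpressionMatrix:
    """Keep genes detected (p < alpha) in treated samples.

    ``scope='any_treated'`` keeps a gene detected in at least one treated
    sample; ``'all_treated'`` requires detection in every treated sample.
    Gene order is preserved.
    """
    if m.detection_p is None:
        raise ValueError("filter_detected requires detection p-values")
    if scope not in ("any_treated", "all_treated"):
        raise ValueError(f"unknown scope {scope!r}")
    treated = [s for s in design.treated_samples() if s in m.values.columns]
    if not treated:
        raise ValueError("design contains no treated samples present in the matrix")
    detected = m.detection_p[treated] < alpha
    keep = detected.any(axis=1) if scope == "any_treated" else detected.all(axis=1)
    return ExpressionMatrix(
        m.values.loc[keep],
        m.detection_p.loc[keep],
    )


def background_subtract(
    m: ExpressionMatrix,
    method: str = "min_shift",
    floor: float = 1.0,
    control_genes: list[str] | None = None,
) -> ExpressionMatrix:
    """Subtract a per-sample background estimate, clipping at ``floor``.

    ``min_shift`` uses each column's minimum as background and shifts the
    column so its minimum lands exactly at the floor; the floor keeps every
    intensity strictly positive so downstream ratios stay defined.
    ``negative_controls`` uses the mean of tagged control rows per column.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0: zero intensities break fold changes")
    if method == "min_shift":
        adjusted = m.values - m.values.min(axis=0) + floor
        return ExpressionMatrix(adjusted, m.detection_p)
    if method == "negative_controls":
        if not control_genes:
            raise ValueError("negative_controls method requires control_genes")
        missing = [g for g in control_genes if g not in m.values.index]
        if missing:
            raise ValueError(f"control gene(s) not in matrix: {missing}")
        background = m.values.loc[control_genes].mean(axis=0)
        adjusted = (m.values - background).clip(lower=floor)
        return ExpressionMatrix(adjusted, m.detection_p)
    raise ValueError(f"unknown background method {method!r}")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force identical per-sample intensity distributions.

    Each column is replaced by the row-wise mean of the sorted columns,
    assigned by rank; a run of tied values receives the mean of the reference
    values its positions span. Idempotent, and a no-op (with a warning) on a
    single-sample matrix.
    """
    if m.n_samples < 2:
        warnings.warn("quantile normalization skipped: fewer than 2 samples")
        return m.copy()
    X = m.values.to_numpy(dtype=float)
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        normalized = reference.copy()
        # tied input values share the mean of the reference values they span
        sorted_col = col[order]
        i = 0
        n = len(col)
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                normalized[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[order, j] = normalized
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.detection_p)


def _welch_log2_p(treated: np.ndarray, control: np.ndarray) -> float:
    if len(treated) < 2 or len(control) < 2:
        return float("nan")
    with np.errstate(divide="ignore"):
        a, b = np.log2(treated), np.log2(control)
    if np.allclose(a.var(), 0) and np.allclose(b.var(), 0):
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    with warnings.catch_warnings():
        # near-constant replicate groups trip scipy's precision-loss warning
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def condition_fold_changes(
    m: ExpressionMatrix, design: ConditionDesign
) -> dict[Genotype, FoldChangeTable]:
    """Fold change of each treated condition vs. control, per genotype.

    Folds are ratios of linear-scale replicate means; the significance test is
    Welch's two-sided t on log2 intensities and needs >=2 replicates per group.
    """
    results: dict[Genotype, FoldChangeTable] = {}
    for genotype in design.genotypes():
        control = [
            s for s in design.group(genotype, Condition.CONTROL)
            if s in m.values.columns
        ]
        if not control:
            raise ValueError(f"empty control group for genotype {genotype.value}")
        ctrl = m.values[control].to_numpy(dtype=float)
        ctrl_mean = ctrl.mean(axis=1)
        if np.any(ctrl_mean <= 0):
            raise ValueError("control means must be positive; run background_subtract")
        columns: dict[str, np.ndarray] = {}
        for condition, key in _COND_KEY.items():
            samples = [
                s for s in design.group(genotype, condition)
                if s in m.values.columns
            ]
            if not samples:
                continue
            trt = m.values[samples].to_numpy(dtype=float)
            columns[f"{key}_fold"] = trt.mean(axis=1) / ctrl_mean
            columns[f"{key}_p"] = np.array(
                [_welch_log2_p(trt[i], ctrl[i]) for i in range(trt.shape[0])]
            )
        if not columns:
            raise ValueError(
                f"no treated conditions for genotype {genotype.value}"
            )
        data = pd.DataFrame(columns, index=m.values.index)
        results[genotype] = FoldChangeTable(genotype, data)
    return results


def ddct(ct: CtTable) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = target Ct - reference Ct per sample; ddCt is the difference of group
    mean dCts (treated minus control); the linear fold is 2^-ddCt.
    """
    df = ct.data
    groups = set(df["group"])
    if not {"control", "treated"} <= groups:
        raise ValueError("Ct table needs both 'control' and 'treated' groups")
    dct = df["target_ct"].astype(float) - df["reference_ct"].astype(float)
    ddct_value = (
        dct[df["group"] == "treated"].mean() - dct[df["group"] == "control"].mean()
    )
    return float(2.0 ** (-ddct_value))


def percent_input(
    ip_ct: float | np.ndarray,
    input_ct: float | np.ndarray,
    input_fraction: float = 1.0,
) -> float | np.ndarray:
    """ChIP-qPCR enrichment relative to unprecipitated (input) chromatin.

    The input Ct is first adjusted for the fraction of chromatin it represents
    (e.g. a 10% input is 1/0.1 = 10x more concentrated, log2(10) ~ 3.32
    cycles); enrichment = 2^(adjusted input Ct - IP Ct).
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must be in (0, 1]")
    adjusted_input = np.asarray(input_ct, dtype=float) - np.log2(1.0 / input_fraction)
    result = 2.0 ** (adjusted_input - np.asarray(ip_ct, dtype=float))
    return float(result) if np.isscalar(ip_ct) or result.ndim == 0 else result
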