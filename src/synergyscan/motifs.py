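"""Position-weight-matrix promoter scanning and composite-module detection.

A PWM scores a window as the conservation-weighted sum of base frequencies,
normalized between the worst and best attainable scores so the consensus
sequence scores 1 (matrix similarity). The *core* similarity is the same score
restricted to the most conserved contiguous positions of the matrix. Matrices
can be built de novo from site lists by an anchored-tuple procedure: find an
exact k-mer shared by most sites, align on it, then iteratively rescore and
rebuild keeping only well-matching sites.

Composite modules (STAT–NFκB, IRF–NFκB) model cooperative transcription-factor
action: two site classes co-occurring within a bounded distance on the same
promoter.
"""

from __future__ import annotations

import enum
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TFClass",
    "PWM",
    "BindingSiteHit",
    "ModuleCall",
    "PWMBuildResult",
    "column_information_weight",
    "matrix_similarity",
    "core_similarity",
    "build_pwm",
    "scan_promoters",
    "detect_modules",
    "annotate_promoters",
    "pwm_from_consensus",
    "default_class_pwms",
    "write_pwms",
    "read_pwms",
    "reverse_complement",
    "DEFAULT_CLASS_CONSENSUS",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: field-standard consensus strings for the three site classes replacing
#: proprietary matrix libraries: the IFNγ-activated sequence (GAS) bound by
#: STAT1 homodimers, the interferon-stimulated response element bound by
#: IRF-family factors, and the canonical NFκB decameric site.
DEFAULT_CLASS_CONSENSUS = {
    "STAT": "TTCCCGGAA",
    "ISRE": "GGAAAGTGAAAC",
    "NFKB": "GGGACTTTCC",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class TFClass(str, enum.Enum):
    STAT = "STAT"
    ISRE = "ISRE"
    NFKB = "NFKB"
    OTHER = "other"


def column_information_weight(freqs) -> float:
    """Conservation weight of one PWM column: sum_b f_b ln(4 f_b) / ln 4.

    0 for a uniform column, 1 for a fully conserved one; 0·ln 0 := 0.
    """
    f = np.asarray(freqs, dtype=float)
    if not np.isclose(f.sum(), 1.0, atol=1e-6):
        raise ValueError(f"column frequencies must sum to 1, got {f.sum()}")
    nz = f[f > 0]
    return float(np.sum(nz * np.log(4.0 * nz)) / np.log(4.0))


@dataclass
class PWM:
    """Position frequency matrix with per-column information weights.

    ``freq`` is an L×4 grid (columns A, C, G, T) with rows summing to 1;
    ``ci`` the per-position conservation weights; ``core_positions`` the
    contiguous run of ``core_size`` positions with maximal total weight
    (leftmost on ties), used for core-similarity scoring.
    """

    name: str
    tf_class: TFClass
    freq: np.ndarray
    core_size: int = 4
    ci: np.ndarray = field(init=False)
    core_positions: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[1] != 4:
            raise ValueError("freq must be an L x 4 matrix")
        if not np.allclose(self.freq.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each freq row must sum to 1")
        self.ci = np.array([column_information_weight(row) for row in self.freq])
        self.core_positions = self._find_core(self.core_size)

    def _find_core(self, k: int) -> tuple[int, ...]:
        L = len(self)
        if L <= k:
            return tuple(range(L))
        sums = [self.ci[i : i + k].sum() for i in range(L - k + 1)]
        start = int(np.argmax(sums))  # argmax is leftmost on ties
        return tuple(range(start, start + k))

    def __len__(self) -> int:
        return self.freq.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freq.argmax(axis=1))

    @classmethod
    def from_sites(
        cls,
        name: str,
        tf_class: TFClass,
        sites: list[str],
        pseudocount: float = 0.01,
        core_size: int = 4,
    ) -> "PWM":
        """Frequency matrix from equal-length aligned sites, pseudocounted."""
        lengths = {len(s) for s in sites}
        if len(lengths) != 1:
            raise ValueError("aligned sites must share one length")
        L = lengths.pop()
        counts = np.full((L, 4), pseudocount, dtype=float)
        for site in sites:
            for i, base in enumerate(site.upper()):
                if base in _BASE_INDEX and base != "N":
                    counts[i, _BASE_INDEX[base]] += 1.0
                else:  # N spreads evenly
                    counts[i] += 0.25
        freq = counts / counts.sum(axis=1, keepdims=True)
        return cls(name, tf_class, freq, core_size=core_size)


@dataclass(frozen=True)
class BindingSiteHit:
    """A scored PWM match, reported on + strand TSS-relative coordinates."""

    gene_id: str
    pwm_name: str
    tf_class: TFClass
    strand: str
    start: int  # TSS-relative, half-open
    end: int
    mat_sim: float
    core_sim: float
    contains_n: bool = False


@dataclass(frozen=True)
class ModuleCall:
    gene_id: str
    module_type: str  # STAT_NFKB or IRF_NFKB
    members: tuple[BindingSiteHit, BindingSiteHit]
    gap: int


@dataclass
class PWMBuildResult:
    pwm: PWM
    included: list[int]  # indices of sites kept at convergence
    anchor: str
    n_iterations: int


def _score_tables(pwm: PWM, positions: np.ndarray | None = None):
    """Per-position contribution lookup (5 rows: A,C,G,T,N) and raw bounds."""
    idx = np.arange(len(pwm)) if positions is None else np.asarray(positions)
    freq = pwm.freq[idx]
    ci = pwm.ci[idx]
    contrib = np.empty((len(idx), 5))
    contrib[:, :4] = ci[:, None] * freq
    contrib[:, 4] = ci * freq.mean(axis=1)  # N: expected (mean) score
    raw_min = float((ci * freq.min(axis=1)).sum())
    raw_max = float((ci * freq.max(axis=1)).sum())
    return contrib, raw_min, raw_max


def _normalize(raw, raw_min: float, raw_max: float):
    if raw_max - raw_min <= 1e-12:  # zero-information matrix: every window fits
        return np.ones_like(np.asarray(raw, dtype=float))
    return (np.asarray(raw, dtype=float) - raw_min) / (raw_max - raw_min)


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int8, count=len(seq))


def _scan_codes(codes: np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mat_sim, core_sim, contains_n) for every window of a coded sequence."""
    L = len(pwm)
    n_windows = len(codes) - L + 1
    if n_windows <= 0:
        empty = np.empty(0)
        return empty, empty, np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    contrib, lo, hi = _score_tables(pwm)
    raw = contrib[np.arange(L), windows].sum(axis=1)
    mat = _normalize(raw, lo, hi)
    core_idx = np.array(pwm.core_positions, dtype=int)
    c_contrib, c_lo, c_hi = _score_tables(pwm, core_idx)
    c_raw = c_contrib[np.arange(len(core_idx)), windows[:, core_idx]].sum(axis=1)
    core = _normalize(c_raw, c_lo, c_hi)
    has_n = (windows == 4).any(axis=1)
    return mat, core, has_n


def matrix_similarity(pwm: PWM, window: str) -> float:
    """Normalized conservation-weighted score of one window (0–1, consensus = 1)."""
    window = window.upper()
    if len(window) != len(pwm):
        raise ValueError(f"window length {len(window)} != matrix length {len(pwm)}")
    mat, _, _ = _scan_codes(_encode(window), pwm)
    return float(mat[0])


def core_similarity(pwm: PWM, window: str) -> float:
    """Matrix similarity restricted to the matrix's conserved core positions."""
    window = window.upper()
    if len(window) != len(pwm):
        raise ValueError(f"window length {len(window)} != matrix length {len(pwm)}")
    _, core, _ = _scan_codes(_encode(window), pwm)
    return float(core[0])


def _site_kmers(site: str, k: int) -> set[str]:
    fwd = {site[i : i + k] for i in range(len(site) - k + 1)}
    rc = reverse_complement(site)
    rev = {rc[i : i + k] for i in range(len(rc) - k + 1)}
    return {m for m in fwd | rev if "N" not in m}


def build_pwm(
    sites: list[str],
    name: str = "de_novo",
    tf_class: TFClass = TFClass.OTHER,
    tuple_size: int = 8,
    min_tuple_frac: float = 0.60,
    mss_inclusion: float = 0.90,
    max_iter: int = 10,
    pseudocount: float = 0.01,
    core_size: int = 4,
    trim_ci: float = 0.30,
) -> PWMBuildResult:
    """Build a conserved matrix from unaligned sites by anchored-tuple alignment.

    1. find the exact ``tuple_size``-mer present (either strand) in at least
       ``min_tuple_frac`` of the sites; 2. anchor-align the sites containing
    it; 3. build a pseudocounted frequency matrix over the positions covered
    by every anchored site, trimming flanking columns whose information
    weight falls below ``trim_ci`` so the matrix spans only the conserved
    region; 4. rescore all sites and keep those whose best window reaches
    ``mss_inclusion`` matrix similarity; 5. rebuild from the kept windows,
    iterating to a fixed point or ``max_iter``.
    """
    if len(sites) < 5:
        raise ValueError("need at least 5 sites to build a matrix")
    sites = [s.upper() for s in sites]

    counts: dict[str, int] = defaultdict(int)
    for site in sites:
        for kmer in _site_kmers(site, tuple_size):
            counts[kmer] += 1
    if not counts:
        raise ValueError(f"sites shorter than tuple_size={tuple_size}")
    needed = min_tuple_frac * len(sites)
    best_count = max(counts.values())
    if best_count < needed:
        raise ValueError(
            f"no {tuple_size}-mer occurs in {min_tuple_frac:.0%} of sites "
            f"(best covers {best_count}/{len(sites)}); try a smaller tuple"
        )
    anchor = min(k for k, c in counts.items() if c == best_count)
    anchor_rc = reverse_complement(anchor)

    # anchor alignment: orient each containing site so the anchor reads forward
    oriented: list[tuple[int, str, int]] = []  # (site index, oriented seq, anchor pos)
    for i, site in enumerate(sites):
        pos = site.find(anchor)
        if pos >= 0:
            oriented.append((i, site, pos))
            continue
        pos = site.find(anchor_rc)
        if pos >= 0:
            rc = reverse_complement(site)
            oriented.append((i, rc, rc.find(anchor)))
    upstream = min(p for _, _, p in oriented)
    downstream = min(len(s) - p for _, s, p in oriented)
    windows = [s[p - upstream : p + downstream] for _, s, p in oriented]

    included = sorted(i for i, _, _ in oriented)
    pwm = PWM.from_sites(name, tf_class, windows, pseudocount, core_size)
    # keep only the conserved region: drop uninformative flanking columns
    informative = np.nonzero(pwm.ci >= trim_ci)[0]
    if len(informative) >= max(tuple_size, core_size):
        lo, hi = int(informative[0]), int(informative[-1]) + 1
        if hi - lo < len(pwm):
            windows = [w[lo:hi] for w in windows]
            pwm = PWM.from_sites(name, tf_class, windows, pseudocount, core_size)
    prev_windows: set[tuple[str, ...]] = set()
    iterations = 0
    for iterations in range(1, max_iter + 1):
        kept_windows: list[str] = []
        kept_idx: list[int] = []
        L = len(pwm)
        for i, site in enumerate(sites):
            best = None
            for seq in (site, reverse_complement(site)):
                if len(seq) < L:
                    continue
                mat, _, _ = _scan_codes(_encode(seq), pwm)
                j = int(mat.argmax())
                if best is None or mat[j] > best[0]:
                    best = (float(mat[j]), seq[j : j + L])
            if best is not None and best[0] >= mss_inclusion:
                kept_idx.append(i)
                kept_windows.append(best[1])
        if len(kept_windows) < 2:
            break  # matrix collapsed; keep the previous one
        key = tuple(sorted(kept_windows))
        pwm = PWM.from_sites(name, tf_class, kept_windows, pseudocount, core_size)
        included = kept_idx
        if key in prev_windows:
            break
        prev_windows.add(key)
    return PWMBuildResult(pwm=pwm, included=included, anchor=anchor, n_iterations=iterations)


def scan_promoters(
    proms,
    pwms: list[PWM],
    min_core: float = 0.85,
    min_mss: float = 0.80,
) -> list[BindingSiteHit]:
    """Scan both strands of every promoter; emit windows passing both cut-offs.

    Positions are TSS-relative half-open intervals on the + strand, whichever
    strand matched.
    """
    hits: list[BindingSiteHit] = []
    for gene, seq in proms:
        codes = _encode(seq)
        rc_codes = _encode(reverse_complement(seq))
        n = len(seq)
        for pwm in pwms:
            L = len(pwm)
            for strand, strand_codes in (("+", codes), ("-", rc_codes)):
                mat, core, has_n = _scan_codes(strand_codes, pwm)
                for j in np.nonzero((core >= min_core) & (mat >= min_mss))[0]:
                    plus_start = int(j) if strand == "+" else n - int(j) - L
                    start = proms.window_start + plus_start
                    hits.append(
                        BindingSiteHit(
                            gene_id=gene,
                            pwm_name=pwm.name,
                            tf_class=pwm.tf_class,
                            strand=strand,
                            start=start,
                            end=start + L,
                            mat_sim=float(mat[j]),
                            core_sim=float(core[j]),
                            contains_n=bool(has_n[j]),
                        )
                    )
    return hits


def _inner_gap(a: BindingSiteHit, b: BindingSiteHit) -> int:
    if a.start > b.start:
        a, b = b, a
    return max(0, b.start - a.end)


_MODULE_PARTNERS = {
    "STAT_NFKB": TFClass.STAT,
    "IRF_NFKB": TFClass.ISRE,
}


def detect_modules(hits: list[BindingSiteHit], max_gap: int = 100) -> list[ModuleCall]:
    """Call composite modules: a STAT-class (or ISRE-class) hit and an
    NFκB-class hit on the same promoter within ``max_gap`` bp of inner-edge
    distance, order- and strand-agnostic; overlapping hits count as gap 0.
    """
    by_gene: dict[str, list[BindingSiteHit]] = defaultdict(list)
    for h in hits:
        by_gene[h.gene_id].append(h)
    calls: list[ModuleCall] = []
    for gene, gene_hits in by_gene.items():
        nfkb = [h for h in gene_hits if h.tf_class == TFClass.NFKB]
        for module_type, partner_class in _MODULE_PARTNERS.items():
            partners = [h for h in gene_hits if h.tf_class == partner_class]
            for a in partners:
                for b in nfkb:
                    gap = _inner_gap(a, b)
                    if gap <= max_gap:
                        calls.append(ModuleCall(gene, module_type, (a, b), gap))
    return calls


def annotate_promoters(
    proms,
    pwms: list[PWM],
    min_core: float = 0.85,
    min_mss: float = 0.80,
    max_gap: int = 100,
):
    """Per-gene presence table of modules and leftover singleton sites.

    Module columns (STAT_NFKB, IRF_NFKB) are true when the composite is
    called; a singleton class column (ISRE, STAT, NFKB) is true only when the
    class has a hit not already consumed by a reported module — mirroring an
    either/or tabular presentation. The full hit and module lists are
    returned alongside for detail output.
    """
    hits = scan_promoters(proms, pwms, min_core=min_core, min_mss=min_mss)
    modules = detect_modules(hits, max_gap=max_gap)
    consumed: dict[str, set[BindingSiteHit]] = defaultdict(set)
    module_flags: dict[str, set[str]] = defaultdict(set)
    for call in modules:
        module_flags[call.gene_id].add(call.module_type)
        consumed[call.gene_id].update(call.members)
    rows = []
    genes = [g for g, _ in proms]
    for gene in genes:
        free = [h for h in hits if h.gene_id == gene and h not in consumed[gene]]
        rows.append(
            {
                "STAT_NFKB": "STAT_NFKB" in module_flags[gene],
                "IRF_NFKB": "IRF_NFKB" in module_flags[gene],
                "ISRE": any(h.tf_class == TFClass.ISRE for h in free),
                "STAT": any(h.tf_class == TFClass.STAT for h in free),
                "NFKB": any(h.tf_class == TFClass.NFKB for h in free),
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"), dtype=bool)
    return table, hits, modules


def pwm_from_consensus(
    name: str,
    tf_class: TFClass,
    consensus: str,
    strength: float = 0.85,
    core_size: int = 4,
) -> PWM:
    """A matrix concentrating ``strength`` on the consensus base per position."""
    if not (0.25 < strength <= 1.0):
        raise ValueError("strength must be in (0.25, 1]")
    L = len(consensus)
    freq = np.full((L, 4), (1.0 - strength) / 3.0)
    for i, base in enumerate(consensus.upper()):
        freq[i, _BASE_INDEX[base]] = strength
    return PWM(name, tf_class, freq, core_size=core_size)


def default_class_pwms(strength: float = 0.85) -> list[PWM]:
    """Generic STAT/GAS, ISRE and NFκB matrices built from class consensus."""
    return [
        pwm_from_consensus(f"{cls}_generic", TFClass(cls), cons, strength)
        for cls, cons in DEFAULT_CLASS_CONSENSUS.items()
    ]


def write_pwms(pwms: list[PWM], path: str | Path) -> None:
    """Serialize matrices in a JASPAR-style plain-text frequency format."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name} {pwm.tf_class.value}\n")
            for bi, base in enumerate(BASES):
                row = " ".join(f"{v:.6f}" for v in pwm.freq[:, bi])
                fh.write(f"{base} [ {row} ]\n")


def read_pwms(path: str | Path, core_size: int = 4) -> list[PWM]:
    pwms: list[PWM] = []
    name = tf_class = None
    rows: dict[str, list[float]] = {}

    def _flush():
        if name is None:
            return
        if set(rows) != set(BASES):
            raise ValueError(f"matrix {name!r} missing base rows")
        freq = np.array([rows[b] for b in BASES]).T
        pwms.append(PWM(name, tf_class, freq, core_size=core_size))

    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            parts = line[1:].split()
            name = parts[0]
            tf_class = TFClass(parts[1]) if len(parts) > 1 else TFClass.OTHER
            rows = {}
        else:
            m = re.match(r"([ACGT])\s*\[\s*(.*?)\s*\]$", line)
            if not m:
                raise ValueError(f"cannot parse matrix row: {line!r}")
            rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    _flush()
    return pwms
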