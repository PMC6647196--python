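"""FPKM normalization, differential filtering and qPCR quantification.

Differential expression follows the stated decision rule rather than a
full count-model fit: per gene and stage, a two-sample t-test on
log2(FPKM + pseudo) between genotypes, Benjamini–Hochberg adjustment
across genes within the stage, and a call of significant when
``FDR < 0.01`` and ``|log2 ratio| >= 1`` (the boundary ratio of exactly 1
is included). Relative qPCR expression uses the 2^-ΔΔCt method against a
reference gene and a calibrator sample.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DifferentialResult",
    "QpcrMeasurement",
    "fpkm",
    "differential_test",
    "bh_fdr",
    "filter_degs",
    "run_differential",
    "venn_partition",
    "relative_expression",
    "write_expression_tsv",
    "read_expression_tsv",
]

FDR_CUTOFF = 0.01
LFC_CUTOFF = 1.0

_LIBRARY_RE = re.compile(r"^(?P<genotype>\w+?)_(?P<stage>\d+)DPA_rep(?P<rep>\d+)$")


@dataclass(frozen=True)
class DifferentialResult:
    gene_id: str
    stage: int
    log2_ratio: float
    p: float
    fdr: float

    @property
    def significant(self) -> bool:
        return self.fdr < FDR_CUTOFF and abs(self.log2_ratio) >= LFC_CUTOFF


@dataclass(frozen=True)
class QpcrMeasurement:
    sample: str
    target_ct: float
    reference_ct: float
    calibrator: bool = False

    def __post_init__(self) -> None:
        for ct in (self.target_ct, self.reference_ct):
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError("Ct values must be finite and positive")


def fpkm(fragments: float, gene_length: int, library_total: int) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    return fragments * 1e9 / (library_total * gene_length)


def differential_test(
    group_a: Sequence[float], group_b: Sequence[float], pseudo: float = 1.0
) -> tuple[float, float]:
    """(log2 ratio, p) for two replicate FPKM groups.

    The ratio is ``log2((mean_b + pseudo) / (mean_a + pseudo))``; the p
    value comes from a two-sample t-test on log2(FPKM + pseudo). Groups
    with zero variance and equal means are returned with p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    if pseudo <= 0 and (a.mean() == 0 or b.mean() == 0):
        raise ValueError("all-zero group with pseudo = 0")
    log2_ratio = float(np.log2((b.mean() + pseudo) / (a.mean() + pseudo)))
    la, lb = np.log2(a + pseudo), np.log2(b + pseudo)
    if np.allclose(la.var(), 0) and np.allclose(lb.var(), 0):
        p = 1.0 if np.isclose(la.mean(), lb.mean()) else 0.0
    else:
        with warnings.catch_warnings():
            # nearly identical replicates trigger a precision-loss warning;
            # the resulting p is still on the conservative side
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_ind(la, lb, equal_var=True).pvalue)
        if not np.isfinite(p):
            p = 1.0
    return log2_ratio, p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_degs(results: Sequence[DifferentialResult]) -> list[DifferentialResult]:
    """The significant subset: FDR < 0.01 and |log2 ratio| >= 1."""
    return [r for r in results if r.significant]


def run_differential(
    counts: pd.DataFrame,
    lengths: pd.Series,
    baseline: str = "wild",
    pseudo: float = 1.0,
    library_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene per-stage differential table from a fragment-count matrix.

    Columns must be named ``<genotype>_<stage>DPA_rep<k>``. FPKM is
    computed against each library's total mapped fragments
    (``library_totals`` when the matrix is a panel from a larger
    transcriptome, else the column sums); the ratio is oriented mutant
    over ``baseline``; BH adjustment is applied within each stage.
    """
    design = []
    for col in counts.columns:
        m = _LIBRARY_RE.match(col)
        if not m:
            raise ValueError(f"cannot parse library name {col!r}")
        design.append((col, m["genotype"], int(m["stage"]), int(m["rep"])))
    design = pd.DataFrame(design, columns=["library", "genotype", "stage", "rep"])
    genotypes = sorted(design["genotype"].unique())
    if baseline not in genotypes or len(genotypes) != 2:
        raise ValueError(f"expected two genotypes including {baseline!r}, got {genotypes}")
    other = next(g for g in genotypes if g != baseline)

    totals = counts.sum(axis=0) if library_totals is None else library_totals.reindex(counts.columns)
    fpkm_mat = counts * 1e9 / totals / lengths.reindex(counts.index).to_numpy()[:, None]

    frames = []
    for stage, sub in design.groupby("stage"):
        libs_a = sub.loc[sub["genotype"] == baseline, "library"]
        libs_b = sub.loc[sub["genotype"] == other, "library"]
        stats_rows = [
            differential_test(fpkm_mat.loc[g, libs_a], fpkm_mat.loc[g, libs_b], pseudo)
            for g in counts.index
        ]
        df = pd.DataFrame(stats_rows, columns=["log2_ratio", "p"], index=counts.index)
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = (df["fdr"] < FDR_CUTOFF) & (df["log2_ratio"].abs() >= LFC_CUTOFF)
        df.insert(0, "stage", stage)
        df.insert(0, "gene_id", counts.index)
        frames.append(df.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)


def venn_partition(deg_sets: Mapping[str, set]) -> dict[tuple, int]:
    """Counts for every non-empty membership region of up to four sets.

    Keys are tuples of set labels (the region belonging to exactly those
    sets); counts over all regions sum to the size of the union.
    """
    labels = list(deg_sets)
    if len(labels) > 4:
        raise ValueError("at most 4 sets")
    out: dict[tuple, int] = {}
    for k in range(1, len(labels) + 1):
        for members in combinations(labels, k):
            region = set.intersection(*(set(deg_sets[m]) for m in members))
            for other in labels:
                if other not in members:
                    region -= set(deg_sets[other])
            out[tuple(members)] = len(region)
    return out


def relative_expression(sample: QpcrMeasurement, calibrator: QpcrMeasurement) -> float:
    """Fold change by the 2^-ΔΔCt method."""
    delta_sample = sample.target_ct - sample.reference_ct
    delta_cal = calibrator.target_ct - calibrator.reference_ct
    return float(2.0 ** -(delta_sample - delta_cal))


def write_expression_tsv(counts: pd.DataFrame, lengths: pd.Series, path) -> None:
    out = counts.copy()
    out.insert(0, "length_bp", lengths.reindex(counts.index))
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_expression_tsv(path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    lengths = df.pop("length_bp")
    return df, lengths
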