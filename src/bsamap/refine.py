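"""Marker-based interval narrowing and candidate-gene enumeration.

After a pooled genome scan localizes the trait to a broad region,
individually genotyped recombinants narrow it: every individual whose
genotype is known on both sides of a candidate placement constrains where
the causal locus can sit, because under single-locus dominance its
phenotype must match the inferred causal genotype. The tightest pair of
flanking markers bounding all consistent placements is the refined
interval; genes fully contained in it are the candidates, ranked by
differential-expression and variant evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "MarkerLocus",
    "GeneModel",
    "marker_interval",
    "narrow_by_recombinants",
    "NarrowResult",
    "genes_in_interval",
    "rank_candidates",
    "read_markers_tsv",
    "read_genes_tsv",
    "read_genes_gff3",
    "read_genotypes_tsv",
]

GENOTYPE_CODES = ("A", "H", "B", "-")  # wt-hom, het, mut-hom, missing


@dataclass(frozen=True)
class MarkerLocus:
    name: str
    chrom: str
    position: int
    marker_type: str = "SSR"  # "SSR" | "InDel"
    forward_primer: str = ""
    reverse_primer: str = ""
    product_length: int = 0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("marker position must be >= 1")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    cds_length: int = 0
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("gene start must be <= end")
        if self.cds_length < 0:
            raise ValueError("cds_length must be positive")


def marker_interval(a: MarkerLocus, b: MarkerLocus) -> GenomicInterval:
    """Interval between two markers (order-independent)."""
    if a.chrom != b.chrom:
        raise ValueError(f"markers on different chromosomes: {a.chrom} vs {b.chrom}")
    return GenomicInterval(a.chrom, min(a.position, b.position), max(a.position, b.position))


@dataclass(frozen=True)
class NarrowResult:
    interval: GenomicInterval
    left_marker: MarkerLocus
    right_marker: MarkerLocus
    n_constraints: int  # individual-slot constraints evaluated
    n_double_crossover_flags: int


_CONSISTENT = {
    # phenotype -> genotype codes a causal placement may carry
    "dominant": {"fuzzy": {"A"}, "fuzzless": {"H", "B"}},
    "recessive": {"fuzzy": {"A", "H"}, "fuzzless": {"B"}},
}


def narrow_by_recombinants(
    markers: Sequence[MarkerLocus],
    genotypes: pd.DataFrame,
    phenotypes: Sequence[str],
    dominance: str = "dominant",
) -> NarrowResult:
    """Find the tightest flanking-marker pair consistent with every phenotype.

    ``genotypes`` is individuals x markers with codes A (wild homozygote),
    H (heterozygote), B (mutant homozygote) and ``-`` (missing).

    The causal locus is placed, in turn, in each slot between adjacent
    markers. For a given slot, an individual's causal genotype is inferred
    from its nearest non-missing marker calls on each side, assuming at
    most one crossover between adjacent markers: when both flanks agree
    the genotype is known and must be consistent with the phenotype; when
    they disagree the individual is recombinant within the slot and
    imposes no constraint there (nor does an individual with calls on only
    one side). Slots where every constrained individual is consistent form
    a contiguous run; the markers immediately outside that run are the
    tightest flanking pair. Adjacent A/B calls (two obligate crossovers
    between neighbouring markers) are counted and reported as a warning,
    since they violate the single-crossover assumption.
    """
    markers = sorted(markers, key=lambda m: m.position)
    if len(markers) < 2:
        raise ValueError("need at least two markers")
    if len({m.chrom for m in markers}) > 1:
        raise ValueError("markers must share one chromosome")
    names = [m.name for m in markers]
    missing_cols = [n for n in names if n not in genotypes.columns]
    if missing_cols:
        raise ValueError(f"genotype table lacks marker columns: {missing_cols}")
    geno = genotypes[names].to_numpy(dtype=object)
    phen = np.asarray(phenotypes, dtype=object)
    if geno.shape[0] != phen.size:
        raise ValueError("genotypes and phenotypes disagree on individual count")
    bad = set(np.unique(geno)) - set(GENOTYPE_CODES)
    if bad:
        raise ValueError(f"unknown genotype codes: {sorted(bad)}")
    if not ((geno != "-").sum(axis=1) >= 1).all():
        raise ValueError("every individual needs at least one non-missing call")
    consistent = _CONSISTENT[dominance]

    n_ind, n_mark = geno.shape
    n_slots = n_mark - 1
    slot_ok = np.ones(n_slots, dtype=bool)
    n_constraints = 0
    n_flags = 0
    for i in range(n_ind):
        row = geno[i]
        known = np.flatnonzero(row != "-")
        codes = row[known]
        allowed = consistent[str(phen[i])]
        # obligate double crossovers between neighbouring non-missing calls
        n_flags += sum(
            1 for a, b in zip(codes[:-1], codes[1:]) if {a, b} == {"A", "B"}
        )
        for j in range(n_slots):
            left = known[known <= j]
            right = known[known > j]
            if left.size == 0 or right.size == 0:
                continue
            code_l, code_r = row[left[-1]], row[right[0]]
            if code_l != code_r:
                continue  # recombinant spanning this slot: unconstrained
            n_constraints += 1
            if code_l not in allowed:
                slot_ok[j] = False
    if n_flags:
        warnings.warn(
            f"{n_flags} adjacent A/B genotype pairs imply >1 crossover between "
            "neighbouring markers; the single-crossover inference may be unreliable",
            stacklevel=2,
        )
    if not slot_ok.any():
        raise ValueError(
            "no causal placement is consistent with all phenotypes; "
            "suspect genotyping/phenotyping error or a multi-locus trait"
        )
    ok = np.flatnonzero(slot_ok)
    # contiguous run of consistent slots (error-free data yields exactly one);
    # pick the longest run if noise fragments it
    runs, start = [], ok[0]
    for a, b in zip(ok[:-1], ok[1:]):
        if b != a + 1:
            runs.append((start, a))
            start = b
    runs.append((start, ok[-1]))
    first, last = max(runs, key=lambda r: r[1] - r[0])
    left = markers[first]
    right = markers[last + 1]
    return NarrowResult(
        interval=GenomicInterval(left.chrom, left.position, right.position),
        left_marker=left,
        right_marker=right,
        n_constraints=n_constraints,
        n_double_crossover_flags=n_flags,
    )


def genes_in_interval(
    genes: Sequence[GeneModel], interval: GenomicInterval
) -> list[GeneModel]:
    """Genes fully contained in the interval, input order preserved."""
    return [
        g
        for g in genes
        if g.chrom == interval.chrom
        and g.start >= interval.start
        and g.end <= interval.end
    ]


def rank_candidates(
    genes: Sequence[GeneModel],
    deg_flags: Mapping[str, bool],
    variant_evidence: Mapping[str, Sequence] = (),
) -> pd.DataFrame:
    """Tiered candidate report.

    Tier 1: differentially expressed with a coding or promoter variant;
    tier 2: differentially expressed only; tier 3: variant only; tier 4:
    neither. Within a tier, genes are ordered by start position.
    """
    variant_evidence = dict(variant_evidence) if variant_evidence else {}
    known = {g.gene_id for g in genes}
    unknown = (set(deg_flags) | set(variant_evidence)) - known
    if unknown:
        raise ValueError(f"evidence refers to unknown gene ids: {sorted(unknown)}")
    rows = []
    for g in genes:
        de = bool(deg_flags.get(g.gene_id, False))
        evidence = [
            v
            for v in variant_evidence.get(g.gene_id, [])
            if getattr(v, "location_class", None) in ("CDS", "promoter")
        ]
        has_variant = len(evidence) > 0
        tier = 1 if (de and has_variant) else 2 if de else 3 if has_variant else 4
        rows.append(
            {
                "gene_id": g.gene_id,
                "tier": tier,
                "start": g.start,
                "end": g.end,
                "differentially_expressed": de,
                "n_variants": len(evidence),
                "variant_summary": "; ".join(
                    getattr(v, "dna_change", "") or getattr(v, "protein_change", "")
                    for v in evidence
                ),
                "annotation": g.annotation,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["tier", "start"], kind="mergesort")
        .reset_index(drop=True)
    )


def read_markers_tsv(path) -> list[MarkerLocus]:
    df = pd.read_csv(path, sep="\t")
    return [
        MarkerLocus(
            name=str(r["name"]),
            chrom=str(r.get("chrom", "chr1")),
            position=int(r["position"]),
            marker_type=str(r.get("marker_type", "SSR")),
            forward_primer=str(r.get("forward_primer", "") or ""),
            reverse_primer=str(r.get("reverse_primer", "") or ""),
            product_length=int(r.get("product_length", 0) or 0),
        )
        for _, r in df.iterrows()
    ]


def read_genes_tsv(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(
            gene_id=str(r["gene_id"]),
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            strand=str(r.get("strand", "+")),
            cds_length=int(r.get("cds_length", 0) or 0),
            annotation=str(r.get("annotation", "") or ""),
        )
        for _, r in df.iterrows()
    ]


def read_genes_gff3(path) -> list[GeneModel]:
    """Gene records from a GFF3 file (features of type 'gene')."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="merge"
    )
    out = []
    for feat in db.features_of_type("gene", order_by="start"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        note = feat.attributes.get("Note", [""])[0]
        out.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or "+",
                annotation=note,
            )
        )
    return out


def read_genotypes_tsv(path) -> tuple[pd.DataFrame, Optional[pd.Series]]:
    """Individuals x markers genotype codes; returns (genotypes, phenotypes).

    A ``phenotype`` column, if present, is split off and returned
    separately.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    phen = None
    if "phenotype" in df.columns:
        phen = df.pop("phenotype")
    return df, phen
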