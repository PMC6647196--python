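"""Variant consequence calls for candidate genes.

Covers the two kinds of evidence used to separate candidates: coding
insertions (in-frame when the inserted length is a multiple of three,
otherwise a frameshift; an in-frame insertion may still introduce a
premature stop) and substitutions falling in the promoter window upstream
of the transcription start. A light global-alignment diff converts a pair
of amplified sequences into simple substitution/insertion/deletion
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .refine import GeneModel
from .variants import VariantSite

__all__ = [
    "VariantConsequence",
    "classify_coding_insertion",
    "promoter_variants",
    "diff_sequences",
    "apply_variants",
    "SequenceVariant",
]

_VALID = set("ACGT")


@dataclass(frozen=True)
class VariantConsequence:
    gene_id: str
    location_class: str  # "CDS" | "promoter" | "intergenic"
    frame_effect: str  # "in_frame_insertion" | "frameshift" | "substitution" | "none"
    protein_change: str = ""
    dna_change: str = ""
    nonsense: bool = False


def _check_nucleotides(seq: str, what: str) -> None:
    bad = set(seq.upper()) - _VALID
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")


def classify_coding_insertion(
    cds_sequence: str, insert_pos: int, inserted: str, gene_id: str = ""
) -> VariantConsequence:
    """Classify an insertion into a CDS.

    ``insert_pos`` is the 1-based offset within the CDS at which the
    inserted bases begin (so ``insert_pos = 4`` places them at the second
    codon's first base, a codon boundary). An insertion whose length is
    not a multiple of three shifts the reading frame; a codon-boundary
    in-frame insertion adds whole residues, named via the standard genetic
    code. In-frame insertions that create a premature stop in the mutated
    translation are flagged nonsense.
    """
    cds = cds_sequence.upper()
    ins = inserted.upper()
    _check_nucleotides(cds, "CDS")
    _check_nucleotides(ins, "insertion")
    if not ins:
        raise ValueError("inserted sequence is empty")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if not 1 <= insert_pos <= len(cds) + 1:
        raise ValueError("insert_pos must lie within the CDS (1-based)")

    dna_change = f"{insert_pos}ins{ins}"
    if len(ins) % 3 != 0:
        return VariantConsequence(
            gene_id=gene_id,
            location_class="CDS",
            frame_effect="frameshift",
            protein_change=f"frameshift at codon {(insert_pos - 1) // 3 + 1}",
            dna_change=dna_change,
        )

    mutated = cds[: insert_pos - 1] + ins + cds[insert_pos - 1 :]
    original_aa = str(Seq(cds).translate())
    mutated_aa = str(Seq(mutated).translate())
    # premature stop: a stop strictly before the original terminal position
    stop_at = mutated_aa.find("*")
    nonsense = 0 <= stop_at < len(mutated_aa) - 1
    codon = (insert_pos - 1) // 3 + 1
    if (insert_pos - 1) % 3 == 0:
        residues = str(Seq(ins).translate())
        protein_change = f"insertion of {residues} at codon {codon}"
    else:
        # length-3k insertion mid-codon: one codon replaced by several
        protein_change = (
            f"in-frame insertion within codon {codon} "
            f"({original_aa[codon - 1]} -> {mutated_aa[codon - 1 : codon + len(ins) // 3]})"
        )
    return VariantConsequence(
        gene_id=gene_id,
        location_class="CDS",
        frame_effect="in_frame_insertion",
        protein_change=protein_change,
        dna_change=dna_change,
        nonsense=nonsense,
    )


def promoter_variants(
    variants: Sequence[VariantSite],
    gene: GeneModel,
    upstream_window: int = 2000,
) -> list[VariantConsequence]:
    """Substitution variants within the promoter window of a gene.

    The window is the ``upstream_window`` bp immediately upstream of the
    annotated gene start: ``[start - window, start - 1]`` on the + strand,
    ``[end + 1, end + window]`` on the - strand.
    """
    if gene.strand == "+":
        lo, hi = gene.start - upstream_window, gene.start - 1
    else:
        lo, hi = gene.end + 1, gene.end + upstream_window
    out = []
    for v in variants:
        if v.chrom != gene.chrom or not lo <= v.pos <= hi:
            continue
        effect = "substitution" if len(v.ref) == len(v.alt) == 1 else "none"
        out.append(
            VariantConsequence(
                gene_id=gene.gene_id,
                location_class="promoter",
                frame_effect=effect,
                dna_change=f"{v.pos}{v.ref}>{v.alt}",
            )
        )
    return out


@dataclass(frozen=True)
class SequenceVariant:
    """A simple diff record against the first sequence (1-based).

    For substitutions ``pos`` is the substituted base; for insertions
    ``pos`` is the base after which ``alt`` is inserted (0 allows an
    insertion before the first base); for deletions ``ref`` spans the
    deleted bases starting at ``pos``.
    """

    pos: int
    ref: str
    alt: str


def diff_sequences(seq_a: str, seq_b: str) -> list[SequenceVariant]:
    """Global-alignment diff of two sequences into simple variant records.

    Scoring: match +1, mismatch -1, gap open -2, gap extend -1. Applying
    the emitted records to ``seq_a`` (see :func:`apply_variants`)
    reconstructs ``seq_b`` exactly; identical inputs give an empty list.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return []
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    # walk the aligned column pairs
    out: list[SequenceVariant] = []
    ia = ib = 0  # consumed prefix of a / b
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        if ia < sa and ib < sb:
            # unaligned stretch on both sides: a block substitution
            out.append(SequenceVariant(pos=ia + 1, ref=a[ia:sa], alt=b[ib:sb]))
        elif ia < sa:  # deletion from a
            out.append(SequenceVariant(pos=ia + 1, ref=a[ia:sa], alt=""))
        elif ib < sb:  # insertion after a[ia - 1]
            out.append(SequenceVariant(pos=ia, ref="", alt=b[ib:sb]))
        for k in range(ea - sa):  # aligned (possibly mismatching) block
            if a[sa + k] != b[sb + k]:
                out.append(SequenceVariant(pos=sa + k + 1, ref=a[sa + k], alt=b[sb + k]))
        ia, ib = ea, eb
    if ia < len(a) and ib < len(b):
        out.append(SequenceVariant(pos=ia + 1, ref=a[ia:], alt=b[ib:]))
    elif ia < len(a):
        out.append(SequenceVariant(pos=ia + 1, ref=a[ia:], alt=""))
    elif ib < len(b):
        out.append(SequenceVariant(pos=ia, ref="", alt=b[ib:]))
    return out


def apply_variants(seq_a: str, variants: Sequence[SequenceVariant]) -> str:
    """Apply diff records (as emitted by :func:`diff_sequences`) to a sequence."""
    a = seq_a.upper()
    # apply right-to-left so earlier coordinates stay valid
    s = a
    for v in sorted(variants, key=lambda v: (v.pos, len(v.ref)), reverse=True):
        if v.ref and v.alt:  # substitution
            if s[v.pos - 1 : v.pos - 1 + len(v.ref)] != v.ref:
                raise ValueError(f"ref mismatch at {v.pos}")
            s = s[: v.pos - 1] + v.alt + s[v.pos - 1 + len(v.ref) :]
        elif v.ref:  # deletion
            if s[v.pos - 1 : v.pos - 1 + len(v.ref)] != v.ref:
                raise ValueError(f"ref mismatch at {v.pos}")
            s = s[: v.pos - 1] + s[v.pos - 1 + len(v.ref) :]
        else:  # insertion after pos
            s = s[: v.pos] + v.alt + s[v.pos :]
    return s
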