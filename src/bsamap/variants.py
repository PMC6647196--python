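"""Per-pool variant sites and VCF 4.2 round-tripping.

A :class:`VariantSite` is one biallelic site with (ref, alt) read depths for
the four sequenced pools: the two parents and the two phenotype-selected
bulks. The alt allele is, by construction of the simulator and the
informative-site filter, the mutant-parent allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

POOLS = ("parent_wt", "parent_mut", "fuzzy", "fuzzless")

__all__ = ["POOLS", "VariantSite", "write_vcf", "read_vcf", "sites_to_frame"]


@dataclass
class VariantSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    var_class: str = "SNP"  # "SNP" | "InDel"
    depths: dict = field(default_factory=dict)  # pool -> (ref_depth, alt_depth)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        for pool, (r, a) in self.depths.items():
            if r < 0 or a < 0:
                raise ValueError(f"negative depth for pool {pool!r}")

    def total_depth(self, pool: str) -> int:
        r, a = self.depths[pool]
        return r + a

    def alt_fraction(self, pool: str) -> float:
        r, a = self.depths[pool]
        if r + a == 0:
            raise ZeroDivisionError(f"zero depth in pool {pool!r} at {self.chrom}:{self.pos}")
        return a / (r + a)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=bsamap
##contig=<ID={chrom},length={length}>
##INFO=<ID=VC,Number=1,Type=String,Description="Variant class (SNP or InDel)">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(sites: Sequence[VariantSite], path, contig_length: int | None = None) -> None:
    """Write sites as plain-text VCF 4.2, one sample column per pool (AD field)."""
    if not sites:
        raise ValueError("no sites to write")
    chrom = sites[0].chrom
    if contig_length is None:
        contig_length = max(s.pos for s in sites)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=chrom, length=contig_length, samples="\t".join(POOLS)))
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            cols = [s.chrom, str(s.pos), ".", s.ref, s.alt, ".", "PASS", f"VC={s.var_class}", "AD"]
            for pool in POOLS:
                r, a = s.depths.get(pool, (0, 0))
                cols.append(f"{r},{a}")
            fh.write("\t".join(cols) + "\n")


def read_vcf(path, pool_samples: dict | None = None) -> list[VariantSite]:
    """Read a pooled VCF via cyvcf2.

    Parameters
    ----------
    pool_samples
        Optional mapping of pool name -> VCF sample name, for files whose
        sample columns are not literally named after the pools.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pool_samples = pool_samples or {p: p for p in POOLS}
    idx = {}
    for pool, sample in pool_samples.items():
        if sample not in samples:
            raise ValueError(f"sample {sample!r} (pool {pool!r}) not in VCF samples {samples}")
        idx[pool] = samples.index(sample)
    out = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue  # biallelic sites only
        ad = v.format("AD")
        vc = v.INFO.get("VC")
        if vc is None:
            vc = "SNP" if len(v.REF) == 1 and len(v.ALT[0]) == 1 else "InDel"
        depths = {
            pool: (int(max(ad[i, 0], 0)), int(max(ad[i, 1], 0))) for pool, i in idx.items()
        }
        out.append(
            VariantSite(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0], var_class=vc, depths=depths
            )
        )
    return out


def sites_to_frame(sites: Iterable[VariantSite]) -> pd.DataFrame:
    """Flatten sites into a DataFrame (one row per site, depth column per pool)."""
    rows = []
    for s in sites:
        row = {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt, "var_class": s.var_class}
        for pool in POOLS:
            r, a = s.depths.get(pool, (0, 0))
            row[f"{pool}_ref"] = r
            row[f"{pool}_alt"] = a
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        df[[c for c in df.columns if c.endswith(("_ref", "_alt"))]] = df[
            [c for c in df.columns if c.endswith(("_ref", "_alt"))]
        ].astype(np.int64)
    return df
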