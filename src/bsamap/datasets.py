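"""Bundled reference tables for the A08 fuzzless-locus mapping experiment."""

from __future__ import annotations

from importlib import resources

from .refine import GeneModel, MarkerLocus, read_genes_tsv, read_markers_tsv
from .segregation import SegregationTable, read_counts_tsv

__all__ = ["load_linked_markers", "load_candidate_orfs", "load_segregation_counts"]


def _data_path(name: str):
    return resources.files("bsamap.data").joinpath(name)


def load_linked_markers() -> list[MarkerLocus]:
    """The 17 SSR/InDel markers linked to the fuzzless locus on A08."""
    with resources.as_file(_data_path("linked_markers_a08.tsv")) as p:
        return read_markers_tsv(p)


def load_candidate_orfs() -> list[GeneModel]:
    """The seven ORFs annotated inside the SSR82–InDel9 interval."""
    with resources.as_file(_data_path("candidate_region_orfs.tsv")) as p:
        return read_genes_tsv(p)


def load_segregation_counts() -> list[SegregationTable]:
    """Observed F2 and BC1 phenotype counts with their expected ratios."""
    with resources.as_file(_data_path("segregation_counts.tsv")) as p:
        return read_counts_tsv(p)
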