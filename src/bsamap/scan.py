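"""Bulked-segregant genome-scan statistics, track fitting and region calling.

The scan works on biallelic sites carrying per-pool (ref, alt) read depths,
where the alt allele is the mutant-parent allele:

* SNP-index of a pool: alt fraction ``alt / (ref + alt)``.
* ΔSNP-index: ``index(fuzzless) - index(fuzzy)``; with this orientation the
  causal peak is positive, with a ceiling of 2/3 for a dominant trait and
  phenotype-selected F2 pools.
* Euclidean distance (ED): distance between the two pools' allele-frequency
  vectors (4 nucleotides for SNPs, {ref, alt} for InDels), optionally
  raised to a power. For a biallelic site ED(power 1) = sqrt(2)|Δf|, so it
  lies in [0, sqrt(2)] and trends toward 0 away from the causal locus.

Raw per-site values are noisy; a tricube-weighted local mean (degree-0
local regression over a base-pair window) produces the fitted track, the
genome-wide threshold is ``median + 3 * sample SD`` of the fitted values,
and maximal runs of fitted values above the threshold become candidate
regions, which can be intersected across statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .intervals import GenomicInterval, intersect_regions
from .variants import VariantSite

__all__ = [
    "IndexTrack",
    "filter_informative_sites",
    "snp_index",
    "delta_snp_index",
    "euclidean_distance",
    "build_track",
    "fit_track",
    "threshold_median_3sd",
    "call_regions",
    "ScanResult",
    "scan_sites",
    "plot_scan",
]


@dataclass
class IndexTrack:
    """Ordered per-site statistic values along one chromosome."""

    chrom: str
    positions: np.ndarray  # bp, strictly ascending
    raw: np.ndarray
    statistic: str  # "ED" | "delta_snp_index"
    fitted: Optional[np.ndarray] = None
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.raw = np.asarray(self.raw, dtype=np.float64)
        if self.positions.size != self.raw.size:
            raise ValueError("positions and raw must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly ascending")
        if self.statistic == "ED" and self.raw.size and self.raw.min() < 0:
            raise ValueError("ED values must be non-negative")
        if (
            self.statistic == "delta_snp_index"
            and self.raw.size
            and (self.raw.min() < -1 or self.raw.max() > 1)
        ):
            raise ValueError("delta SNP-index values must lie in [-1, 1]")

    def __len__(self) -> int:
        return self.positions.size


def filter_informative_sites(
    sites: Sequence[VariantSite],
    min_depth: int = 10,
    min_parent_depth: int = 10,
) -> list[VariantSite]:
    """Keep sites where the parents are consistent opposite homozygotes.

    The mutant parent must show alt fraction >= 0.9 and the wild parent
    <= 0.1, each at depth >= ``min_parent_depth``; both phenotype pools
    must reach total depth >= ``min_depth``.
    """
    kept = []
    for s in sites:
        try:
            if s.total_depth("parent_mut") < min_parent_depth:
                continue
            if s.total_depth("parent_wt") < min_parent_depth:
                continue
            if s.alt_fraction("parent_mut") < 0.9 or s.alt_fraction("parent_wt") > 0.1:
                continue
            if s.total_depth("fuzzy") < min_depth or s.total_depth("fuzzless") < min_depth:
                continue
        except (KeyError, ZeroDivisionError):
            continue
        kept.append(s)
    return kept


def snp_index(site: VariantSite, pool: str) -> float:
    """Alt-allele (mutant-parent allele) read fraction in one pool."""
    return site.alt_fraction(pool)


def delta_snp_index(site: VariantSite) -> float:
    """SNP-index difference, fuzzless minus fuzzy; causal peak is positive."""
    return snp_index(site, "fuzzless") - snp_index(site, "fuzzy")


def _allele_freq_vector(site: VariantSite, pool: str) -> np.ndarray:
    f = site.alt_fraction(pool)
    if site.var_class == "SNP":
        vec = dict.fromkeys("ACGT", 0.0)
        vec[site.ref[0]] = vec.get(site.ref[0], 0.0) + (1 - f)
        vec[site.alt[0]] = vec.get(site.alt[0], 0.0) + f
        return np.array([vec[b] for b in "ACGT"])
    return np.array([1 - f, f])  # {ref, alt} alleles for InDels


def euclidean_distance(site: VariantSite, power: int = 1) -> float:
    """Distance between the pools' allele-frequency vectors, to a power."""
    if power < 1:
        raise ValueError("power must be a positive integer")
    diff = _allele_freq_vector(site, "fuzzless") - _allele_freq_vector(site, "fuzzy")
    return float(np.sqrt(np.sum(diff**2)) ** power)


def build_track(
    sites: Sequence[VariantSite], statistic: str = "delta_snp_index", ed_power: int = 1
) -> IndexTrack:
    """Assemble the raw per-site track for one statistic.

    Sites must share a chromosome and already have passed the depth
    filter (zero-depth phenotype pools are rejected here).
    """
    if not sites:
        raise ValueError("no sites")
    chroms = {s.chrom for s in sites}
    if len(chroms) > 1:
        raise ValueError(f"sites span multiple chromosomes: {sorted(chroms)}")
    ordered = sorted(sites, key=lambda s: s.pos)
    positions = np.array([s.pos for s in ordered], dtype=np.float64)
    if statistic == "delta_snp_index":
        raw = np.array([delta_snp_index(s) for s in ordered])
    elif statistic == "ED":
        raw = np.array([euclidean_distance(s, power=ed_power) for s in ordered])
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return IndexTrack(chrom=ordered[0].chrom, positions=positions, raw=raw, statistic=statistic)


def fit_track(track: IndexTrack, window: float = 500_000) -> IndexTrack:
    """Tricube-weighted local mean (degree-0 local regression) of the raw track.

    For each site, neighbours within ``window / 2`` bp contribute with
    weight ``(1 - (d / (window / 2))^3)^3``; windows truncate at the
    chromosome ends. Every fitted value is a convex combination of raw
    values, so it stays within the raw range of its window.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    if len(track) < 2:
        return replace(track, fitted=track.raw.copy())
    if window <= 0:
        raise ValueError("window must be positive")
    pos, raw = track.positions, track.raw
    half = window / 2.0
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    fitted = np.empty_like(raw)
    for i in range(pos.size):
        sl = slice(lo[i], hi[i])
        d = np.abs(pos[sl] - pos[i]) / half if half > 0 else np.zeros(hi[i] - lo[i])
        w = (1 - np.minimum(d, 1.0) ** 3) ** 3
        wsum = w.sum()
        if wsum <= 0:  # isolated site (only itself at weight ~0 cannot happen: d=0 -> w=1)
            fitted[i] = raw[i]
        else:
            fitted[i] = float(np.dot(w, raw[sl]) / wsum)
    return replace(track, fitted=fitted)


def threshold_median_3sd(track: IndexTrack) -> float:
    """``median + 3 * sample SD`` of all fitted points, genome-wide."""
    if track.fitted is None:
        raise ValueError("track has no fitted values; run fit_track first")
    if track.fitted.size < 2:
        raise ValueError("need at least 2 fitted points")
    fitted = track.fitted
    return float(np.median(fitted) + 3.0 * np.std(fitted, ddof=1))


def call_regions(
    track: IndexTrack, threshold: float, merge_gap: float = 100_000
) -> list[GenomicInterval]:
    """Maximal runs of sites with fitted >= threshold, as genomic intervals.

    Runs whose bp gap (distance between the last site of one run and the
    first site of the next) is smaller than ``merge_gap`` are merged. Each
    interval spans the first to the last site position of its run.
    """
    if track.fitted is None:
        raise ValueError("track has no fitted values; run fit_track first")
    above = track.fitted >= threshold
    if not above.any():
        return []
    pos = track.positions
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size - 1)
    runs = list(zip(starts, ends))
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if pos[s] - pos[pe] < merge_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return [
        GenomicInterval(track.chrom, int(pos[s]), int(pos[e])) for s, e in merged
    ]


@dataclass
class ScanResult:
    """Tracks, thresholds and regions for a full two-statistic scan."""

    tracks: dict = field(default_factory=dict)  # key -> IndexTrack
    thresholds: dict = field(default_factory=dict)
    regions: dict = field(default_factory=dict)  # key -> list[GenomicInterval]
    intersected: list = field(default_factory=list)


def scan_sites(
    sites: Sequence[VariantSite],
    window: float = 500_000,
    ed_power: int = 1,
    merge_gap: float = 100_000,
    min_depth: int = 10,
    min_parent_depth: int = 10,
    by_class: bool = False,
    two_sided: bool = False,
) -> ScanResult:
    """Run the ED and ΔSNP-index scans and intersect their candidate regions.

    With ``by_class=True`` SNPs and InDels are scanned as separate tracks
    (separate thresholds), and the final region list is the intersection
    over every (statistic, class) region set; otherwise all sites form one
    track per statistic. ``two_sided`` scans |ΔSNP-index| instead of the
    signed value, for an unknown parental orientation.
    """
    informative = filter_informative_sites(sites, min_depth, min_parent_depth)
    if not informative:
        raise ValueError("no informative sites after filtering")
    groups = (
        {
            vc: [s for s in informative if s.var_class == vc]
            for vc in ("SNP", "InDel")
            if any(s.var_class == vc for s in informative)
        }
        if by_class
        else {"all": informative}
    )
    result = ScanResult()
    for vc, group in groups.items():
        for statistic in ("ED", "delta_snp_index"):
            track = build_track(group, statistic, ed_power=ed_power)
            if statistic == "delta_snp_index" and two_sided:
                track = replace(track, raw=np.abs(track.raw))
            track = fit_track(track, window=window)
            thr = threshold_median_3sd(track)
            track.threshold = thr
            key = f"{statistic}/{vc}"
            result.tracks[key] = track
            result.thresholds[key] = thr
            result.regions[key] = call_regions(track, thr, merge_gap=merge_gap)
    intersected: list[GenomicInterval] | None = None
    for regions in result.regions.values():
        intersected = regions if intersected is None else intersect_regions(intersected, regions)
    result.intersected = intersected or []
    return result


def plot_scan(result: ScanResult, path) -> None:
    """Static figure of fitted tracks with their threshold lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(result.tracks)
    fig, axes = plt.subplots(n, 1, figsize=(9, 2.4 * n), sharex=True, squeeze=False)
    for ax, (key, track) in zip(axes.ravel(), sorted(result.tracks.items())):
        mb = track.positions / 1e6
        ax.plot(mb, track.raw, ".", ms=1.5, color="0.7", label="raw")
        if track.fitted is not None:
            ax.plot(mb, track.fitted, "-", color="C0", lw=1.2, label="fitted")
        if track.threshold is not None:
            ax.axhline(track.threshold, color="C3", ls="--", lw=1, label="threshold")
        for iv in result.regions.get(key, []):
            ax.axvspan(iv.start / 1e6, iv.end / 1e6, color="C1", alpha=0.2)
        ax.set_ylabel(key, fontsize=8)
        ax.legend(fontsize=7, loc="upper right")
    axes.ravel()[-1].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
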