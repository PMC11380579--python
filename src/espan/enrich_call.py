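"""Desk-scale BrdU-enriched-region and nucleosome-dyad callers.

These are deliberately simple internal stand-ins for the external peak and
nucleosome callers commonly used upstream of eSPAN analysis (not ports of
them): a Poisson local-lambda enrichment test with Benjamini-Hochberg
correction for BrdU regions, and smoothed-local-maxima dyad calling for
nucleosomes.  Externally produced region/nucleosome BED files can be
imported instead via :func:`load_regions` / :func:`load_nucleosomes`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .strand_io import StrandCoverage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichedRegion:
    chrom: str
    start: int  # bp, half-open
    end: int
    fold_enrichment: float
    score: float  # -log10 of the smallest BH-adjusted Poisson tail q in the region


@dataclass(frozen=True)
class NucleosomeCall:
    chrom: str
    dyad: int  # bp
    occupancy: float  # smoothed coverage height at the dyad


def call_brdu_regions(
    brdu_cov: StrandCoverage,
    input_cov: StrandCoverage,
    min_fold: float = 2.0,
    alpha: float = 0.01,
    merge_gap: int = 2,
    min_width: int = 500,
) -> list[EnrichedRegion]:
    """Call BrdU-enriched regions from pooled-strand coverage vs input.

    Per bin, the expected count is the input count scaled by the library-size
    ratio, floored at the global background (mean BrdU count per bin).  A bin
    is significant when its count is at least ``min_fold`` times expected and
    its upper Poisson tail probability survives Benjamini-Hochberg control at
    ``alpha``.  Significant bins separated by at most ``merge_gap`` bins are
    merged; regions shorter than ``min_width`` bp are dropped.
    """
    if brdu_cov.bin_width != input_cov.bin_width or brdu_cov.n_bins != input_cov.n_bins:
        raise ValueError("BrdU and input coverage must share binning")
    if brdu_cov.chrom != input_cov.chrom:
        raise ValueError("BrdU and input coverage are from different chromosomes")
    if input_cov.library_size == 0:
        raise ValueError("input library is empty")
    count = brdu_cov.pooled().astype(float)
    expected = input_cov.pooled() * (brdu_cov.library_size / input_cov.library_size)
    lam0 = count.sum() / len(count)  # global background
    lam = np.maximum(expected, lam0)
    pvals = stats.poisson.sf(count - 1, lam)  # P(X >= count | lam)
    qvals = stats.false_discovery_control(pvals, method="bh")
    sig = (count >= min_fold * lam) & (qvals <= alpha)

    regions: list[EnrichedRegion] = []
    bw = brdu_cov.bin_width
    idx = np.flatnonzero(sig)
    if len(idx) == 0:
        return regions
    breaks = np.flatnonzero(np.diff(idx) > merge_gap + 1) + 1
    for grp in np.split(idx, breaks):
        a, b = int(grp[0]), int(grp[-1]) + 1
        start, end = a * bw, min(b * bw, brdu_cov.chrom_length)
        if end - start < min_width:
            continue
        fold = count[a:b].sum() / max(lam[a:b].sum(), 1e-300)
        q = max(float(qvals[grp].min()), 1e-300)
        regions.append(
            EnrichedRegion(
                chrom=brdu_cov.chrom,
                start=start,
                end=end,
                fold_enrichment=float(fold),
                score=float(-np.log10(q)),
            )
        )
    logger.info(
        "called %d BrdU-enriched regions (%d significant bins)", len(regions), len(idx)
    )
    return regions


def call_nucleosomes(
    mnase_cov: StrandCoverage,
    smooth_window: int = 60,
    min_separation: int = 120,
    min_occupancy: float = 0.0,
) -> list[NucleosomeCall]:
    """Call nucleosome dyads as smoothed local maxima of pooled coverage.

    Coverage is smoothed with a centered moving average of ~``smooth_window``
    bp; local maxima are accepted greedily by descending height subject to a
    ``min_separation`` bp exclusion zone, ties broken toward the smaller
    coordinate.  Requires fine binning (``bin_width`` <= 20 bp).
    """
    bw = mnase_cov.bin_width
    if bw > 20:
        raise ValueError(f"nucleosome calling needs bin_width <= 20 bp (got {bw})")
    if smooth_window < bw:
        raise ValueError(f"smooth_window ({smooth_window}) must be >= bin_width ({bw})")
    raw = mnase_cov.pooled().astype(float)
    k = max(1, int(round(smooth_window / bw)))
    if k % 2 == 0:
        k += 1
    kernel = np.ones(k) / k
    smoothed = np.convolve(raw, kernel, mode="same")

    left = np.empty_like(smoothed)
    right = np.empty_like(smoothed)
    left[0] = -np.inf
    left[1:] = smoothed[:-1]
    right[-1] = -np.inf
    right[:-1] = smoothed[1:]
    # strict on the left makes the leftmost bin of a plateau the candidate
    candidates = np.flatnonzero((smoothed > left) & (smoothed >= right) & (smoothed > 0))
    if min_occupancy > 0:
        candidates = candidates[smoothed[candidates] >= min_occupancy]
    # greedy by descending height; ties toward the smaller coordinate
    order = candidates[np.lexsort((candidates, -smoothed[candidates]))]
    accepted: list[int] = []
    accepted_pos: list[int] = []
    min_sep_bins = min_separation / bw
    import bisect

    for c in order:
        j = bisect.bisect_left(accepted_pos, c)
        if j > 0 and c - accepted_pos[j - 1] < min_sep_bins:
            continue
        if j < len(accepted_pos) and accepted_pos[j] - c < min_sep_bins:
            continue
        bisect.insort(accepted_pos, c)
        accepted.append(c)
    calls = [
        NucleosomeCall(
            chrom=mnase_cov.chrom,
            dyad=int(c) * bw + bw // 2,
            occupancy=float(smoothed[c]),
        )
        for c in sorted(accepted)
    ]
    logger.info("called %d nucleosomes", len(calls))
    return calls


# --------------------------------------------------------------------------
# BED import/export
# --------------------------------------------------------------------------


def write_regions_bed(regions: list[EnrichedRegion], path: str) -> None:
    """Regions as BED6; score column carries -log10 q."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i + 1}\t{r.score:.4g}\t.\n")


def load_regions(path: str) -> list[EnrichedRegion]:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            score = float(f[4]) if len(f) > 4 else 0.0
            regions.append(
                EnrichedRegion(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    fold_enrichment=float("nan"), score=score,
                )
            )
    return regions


def write_nucleosomes_bed(calls: list[NucleosomeCall], path: str, footprint: int = 147) -> None:
    """Nucleosome calls as BED6 footprints; score column carries occupancy."""
    half = footprint // 2
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            fh.write(
                f"{c.chrom}\t{max(c.dyad - half, 0)}\t{c.dyad + footprint - half}"
                f"\tnuc_{i + 1}\t{c.occupancy:.4g}\t.\n"
            )


def load_nucleosomes(path: str) -> list[NucleosomeCall]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            start, end = int(f[1]), int(f[2])
            occ = float(f[4]) if len(f) > 4 else float("nan")
            calls.append(NucleosomeCall(chrom=f[0], dyad=(start + end) // 2, occupancy=occ))
    return calls
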