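"""Ingest aligned reads, assign strands, and build binned strand coverage.

Strand convention: a fragment belongs to the Watson strand when its
first-in-pair (or single-end) read aligned forward, and to the Crick strand
when the reverse-strand flag bit (0x10) is set — the standard readout of
strand-preserving single-stranded libraries.  Internally all coordinates are
0-based half-open; pysam handles the SAM 1-based conversion at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pysam

from .sim_fork import ReadSet

logger = logging.getLogger(__name__)

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


def assign_strand(flag: int) -> str:
    """Watson/Crick assignment from a SAM flag.

    Only first-in-pair (or single-end) flags define the fragment strand;
    passing a second-in-pair flag alone is an error.
    """
    if flag & FLAG_PAIRED and flag & FLAG_READ2:
        raise ValueError(
            f"flag {flag} is second-in-pair; fragment strand is defined by first-in-pair"
        )
    return "crick" if flag & FLAG_REVERSE else "watson"


def read_stranded_alignments(
    sam_path: str,
    min_mapq: int = 20,
    require_proper_pairs: bool = True,
    sample: str = "unknown",
    replicate: int = 0,
) -> ReadSet:
    """Load one fragment per passing read (pair) from a SAM/BAM file.

    Paired data yield exactly one record per passing pair, spanning the whole
    fragment (derived from the first-in-pair position and template length);
    unpaired data yield one record per passing read.  Unmapped, secondary and
    supplementary records are dropped; drop reasons are counted in the
    returned set's ``drops`` and logged.
    """
    starts: list[int] = []
    ends: list[int] = []
    watson: list[bool] = []
    drops = {
        "unmapped": 0,
        "secondary_supplementary": 0,
        "low_mapq": 0,
        "not_proper_pair": 0,
        "mate_unmapped": 0,
        "mate_ref_mismatch": 0,
    }
    chrom = None
    with pysam.AlignmentFile(sam_path, check_sq=True) as fh:
        if fh.header.get("SQ") is None or len(fh.header["SQ"]) == 0:
            raise ValueError(f"{sam_path}: SAM header lacks @SQ lines")
        for rec in fh:
            if rec.is_unmapped:
                drops["unmapped"] += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                drops["secondary_supplementary"] += 1
                continue
            if rec.mapping_quality < min_mapq:
                drops["low_mapq"] += 1
                continue
            if rec.is_paired:
                if not rec.is_read1:
                    continue  # the pair is represented by its first-in-pair read
                if require_proper_pairs and not rec.is_proper_pair:
                    drops["not_proper_pair"] += 1
                    continue
                if rec.mate_is_unmapped:
                    drops["mate_unmapped"] += 1
                    continue
                if rec.next_reference_id != rec.reference_id:
                    drops["mate_ref_mismatch"] += 1
                    continue
                tlen = rec.template_length
                if tlen != 0:
                    left = min(rec.reference_start, rec.next_reference_start)
                    start, end = left, left + abs(tlen)
                else:  # degenerate pair: fall back to the read span
                    start, end = rec.reference_start, rec.reference_end
                strand_flag = rec.flag
            else:
                start, end = rec.reference_start, rec.reference_end
                strand_flag = rec.flag
            if chrom is None:
                chrom = rec.reference_name
            starts.append(start)
            ends.append(end)
            watson.append(assign_strand(strand_flag) == "watson")
    n_dropped = sum(drops.values())
    if n_dropped:
        logger.warning(
            "%s: dropped %d records (%s)",
            sam_path,
            n_dropped,
            ", ".join(f"{k}={v}" for k, v in drops.items() if v),
        )
    return ReadSet(
        chrom=chrom or "unknown",
        start=np.asarray(starts, dtype=np.int64),
        end=np.asarray(ends, dtype=np.int64),
        watson=np.asarray(watson, dtype=bool),
        sample=sample,
        replicate=replicate,
        drops=drops,
    )


# --------------------------------------------------------------------------
# binned strand coverage
# --------------------------------------------------------------------------


@dataclass
class StrandCoverage:
    """Per-bin Watson/Crick fragment counts for one sample.

    Bins tile ``[0, chrom_length)`` half-open at ``bin_width``; each retained
    fragment contributes one count to the bin containing its midpoint.
    """

    chrom: str
    chrom_length: int
    bin_width: int
    counts_watson: np.ndarray  # int64, one entry per bin
    counts_crick: np.ndarray
    library_size: int
    sample: str = "unknown"
    replicate: int = 0
    n_out_of_range: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.counts_watson)

    def pooled(self) -> np.ndarray:
        return self.counts_watson + self.counts_crick

    def cpm(self, strand: str) -> np.ndarray:
        """Counts per million assigned fragments for one strand."""
        counts = self.counts_watson if strand == "watson" else self.counts_crick
        if self.library_size == 0:
            return np.zeros_like(counts, dtype=float)
        return counts * (1e6 / self.library_size)

    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.bin_width

    def write_bedgraph(self, prefix: str) -> tuple[str, str]:
        """Write per-strand bedGraph files ``<prefix>.{watson,crick}.bedgraph``."""
        paths = []
        for strand, counts in (("watson", self.counts_watson), ("crick", self.counts_crick)):
            path = f"{prefix}.{strand}.bedgraph"
            _write_bedgraph_track(path, self.chrom, self.chrom_length, self.bin_width, counts)
            paths.append(path)
        return tuple(paths)


def _write_bedgraph_track(path, chrom, chrom_length, bin_width, values) -> None:
    values = np.asarray(values)
    with open(path, "w") as fh:
        # merge equal-valued runs; omit zero runs
        change = np.flatnonzero(np.diff(values)) + 1
        bounds = np.concatenate([[0], change, [len(values)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            v = values[a]
            if v == 0:
                continue
            start = int(a) * bin_width
            end = min(int(b) * bin_width, chrom_length)
            fh.write(f"{chrom}\t{start}\t{end}\t{v:g}\n")


def bin_coverage(
    reads: ReadSet,
    chrom_length: int,
    bin_width: int,
    method: str = "midpoint",
) -> StrandCoverage:
    """Binned strand-specific coverage.

    ``method='midpoint'`` (default): each read contributes 1 to the bin
    containing ``floor((start + end) / 2)`` — the simplest rule for
    nucleosome-footprint fragments, and the one under which per-strand counts
    sum exactly to the number of retained reads.  ``method='spread'``: each
    read contributes 1 to every bin it overlaps.  Reads falling entirely
    outside ``[0, chrom_length)`` are dropped and counted.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if method not in ("midpoint", "spread"):
        raise ValueError("method must be 'midpoint' or 'spread'")
    n_bins = -(-chrom_length // bin_width)
    if method == "midpoint":
        mid = (reads.start + reads.end) // 2
        ok = (mid >= 0) & (mid < chrom_length)
    else:
        ok = (reads.end > 0) & (reads.start < chrom_length)
    n_out = int((~ok).sum())
    if n_out:
        logger.warning("%s: %d reads outside [0, %d) dropped", reads.sample, n_out, chrom_length)
    w = reads.watson[ok]
    if method == "midpoint":
        bins = ((reads.start + reads.end) // 2)[ok] // bin_width
        counts_w = np.bincount(bins[w], minlength=n_bins).astype(np.int64)
        counts_c = np.bincount(bins[~w], minlength=n_bins).astype(np.int64)
    else:
        first = np.clip(reads.start[ok] // bin_width, 0, n_bins - 1)
        last = np.clip((reads.end[ok] - 1) // bin_width, 0, n_bins - 1)
        counts_w = np.zeros(n_bins, dtype=np.int64)
        counts_c = np.zeros(n_bins, dtype=np.int64)
        for counts, sel in ((counts_w, w), (counts_c, ~w)):
            # difference-array trick: +1 at first bin, -1 past the last
            delta = np.zeros(n_bins + 1, dtype=np.int64)
            np.add.at(delta, first[sel], 1)
            np.add.at(delta, last[sel] + 1, -1)
            counts[:] = np.cumsum(delta[:-1])
    return StrandCoverage(
        chrom=reads.chrom,
        chrom_length=chrom_length,
        bin_width=bin_width,
        counts_watson=counts_w,
        counts_crick=counts_c,
        library_size=int(ok.sum()),
        sample=reads.sample,
        replicate=reads.replicate,
        n_out_of_range=n_out,
    )


# --------------------------------------------------------------------------
# origins
# --------------------------------------------------------------------------


@dataclass
class OriginSet:
    """Ordered replication-origin anchor points (e.g. early-firing ACSs)."""

    chroms: np.ndarray  # object/str array
    positions: np.ndarray  # int64, 0-based point positions
    labels: np.ndarray  # object/str array

    @property
    def n(self) -> int:
        return len(self.positions)

    def for_chrom(self, chrom: str) -> np.ndarray:
        """Origin point positions on one chromosome (sorted)."""
        return self.positions[self.chroms == chrom]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"chrom": self.chroms, "position": self.positions, "label": self.labels}
        )


def load_origins(bed_path: str) -> OriginSet:
    """Load origin points from a BED3+ file.

    The origin point is the interval midpoint ``floor((start + end) / 2)``,
    0-based; column 4 is kept as the label when present.  Output is sorted by
    (chrom, position) and de-duplicated.
    """
    chroms: list[str] = []
    positions: list[int] = []
    labels: list[str] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{bed_path}:{lineno}: expected >= 3 BED columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(
                    f"{bed_path}:{lineno}: chromEnd ({end}) must exceed chromStart ({start})"
                )
            chroms.append(chrom)
            positions.append((start + end) // 2)
            labels.append(fields[3] if len(fields) > 3 else f"origin_{len(positions)}")
    order = sorted(range(len(positions)), key=lambda i: (chroms[i], positions[i]))
    seen = set()
    keep = []
    for i in order:
        key = (chroms[i], positions[i])
        if key in seen:
            logger.warning("%s: duplicate origin %s:%d dropped", bed_path, chroms[i], positions[i])
            continue
        seen.add(key)
        keep.append(i)
    return OriginSet(
        chroms=np.asarray([chroms[i] for i in keep], dtype=object),
        positions=np.asarray([positions[i] for i in keep], dtype=np.int64),
        labels=np.asarray([labels[i] for i in keep], dtype=object),
    )


def write_origins_bed(origins: OriginSet, path: str) -> None:
    """Write origin points as 1-bp BED6 intervals."""
    with open(path, "w") as fh:
        for c, p, lab in zip(origins.chroms, origins.positions, origins.labels):
            fh.write(f"{c}\t{p}\t{p + 1}\t{lab}\t0\t+\n")
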