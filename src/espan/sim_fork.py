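"""Replication-fork chromatin simulator.

Generates the ground truth against which every downstream stage of the
eSPAN pipeline can be checked by parameter recovery: a single synthetic
chromosome, bidirectional replication from point origins, a BrdU labeling
window bounding nascent DNA, nucleosomes on the two sister chromatids with
parental-mark retention and leading/lagging partitioning, new-mark fill-in,
and strand-tagged nucleosome-footprint reads for all six sample kinds
produced per strain in an eSPAN experiment (input, MNase-BrdU-IP, the two
ChIPs, and the two eSPANs).

Model in brief
--------------
Nucleosome slots sit on a dyad lattice (one slot every ``nucleosome_spacing``
bp; inside a nascent interval the lattice is anchored at the origin).  Before
replication every slot carries one parental-marked nucleosome on the
unreplicated duplex.  Within the nascent interval of a fired origin each
parental nucleosome is independently recycled with probability ``p_retain``,
landing on the leading-strand daughter with probability ``p_lead`` (else the
lagging-strand daughter), or is lost.  Every remaining empty sister slot is
filled with a new-marked nucleosome with probability ``new_fill``.

Reads are nucleosome footprints sampled with replacement, with per-nucleosome
capture weights encoding antibody specificity (``chip_offtarget``) and BrdU-IP
selectivity (``brdu_leakage``: the relative capture weight of non-nascent
chromatin that leaks through the BrdU pulldown — real single-stranded eSPAN
libraries carry such a genome-wide background, and it is what anchors
library-size normalization so that density changes between strains are
observable).  Strand assignment follows bidirectional-fork geometry: on the
right arm of an origin the leading daughter's nascent strand is Watson and the
lagging daughter's is Crick; on the left arm the assignment is mirrored.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# sample kinds and categorical codes
# --------------------------------------------------------------------------

SAMPLE_KINDS = (
    "input",
    "mnase_brdu_ip",
    "chip_parental",
    "chip_new",
    "espan_parental",
    "espan_new",
)
#: samples whose library passed through the BrdU immunoprecipitation
BRDU_SAMPLES = frozenset({"mnase_brdu_ip", "espan_parental", "espan_new"})
_SAMPLE_CODE = {s: i for i, s in enumerate(SAMPLE_KINDS)}

# daughter codes
UNREPLICATED, LEADING, LAGGING = 0, 1, 2
DAUGHTER_NAMES = {UNREPLICATED: "unreplicated", LEADING: "leading", LAGGING: "lagging"}
# mark codes
PARENTAL, NEW = 1, 2
MARK_NAMES = {PARENTAL: "parental", NEW: "new"}
# arm codes
ARM_NONE, ARM_LEFT, ARM_RIGHT = 0, 1, 2
ARM_NAMES = {ARM_NONE: "none", ARM_LEFT: "left", ARM_RIGHT: "right"}


class SimConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


class EmptySampleError(ValueError):
    """Raised when a sample kind has no eligible nucleosomes to sequence."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated strain.

    The defaults describe the reference (wild-type-like) condition used
    throughout the test-suite and the acceptance runs: sparse early-firing
    origins (2.5 Mb spacing via :func:`default_config`), so that 40 minutes
    into the labeling pulse nascent DNA is a small fraction of the genome and
    the BrdU-IP-leakage background dominates eSPAN library size (which is
    what makes between-strain density changes visible after per-library
    normalization); full nucleosome re-occupancy behind the fork
    (``new_fill = 1``); high but incomplete parental recycling
    (``p_retain = 0.9``) with symmetric leading/lagging partitioning
    (``p_lead = 0.5``).
    """

    genome_length: int
    origins: tuple[int, ...]
    chrom_name: str = "chrSim"
    nascent_halfwidth: int = 10_000
    nucleosome_spacing: int = 165
    footprint: int = 147
    p_retain: float = 0.9
    p_lead: float = 0.5
    new_fill: float = 1.0
    chip_offtarget: float = 0.005
    brdu_leakage: float = 0.25
    frag_jitter: float = 10.0
    depth: int = 500_000
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "origins", tuple(int(o) for o in self.origins))
        for name in ("p_retain", "p_lead", "new_fill", "chip_offtarget", "brdu_leakage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name}={v!r} must lie in [0, 1]")
        if self.genome_length <= 0:
            raise SimConfigError("genome_length must be positive")
        if not self.origins:
            raise SimConfigError("at least one origin is required")
        ori = np.asarray(self.origins)
        if np.any(np.diff(ori) <= 0):
            raise SimConfigError("origins must be strictly increasing")
        if ori[0] < 0 or ori[-1] >= self.genome_length:
            bad = ori[(ori < 0) | (ori >= self.genome_length)][0]
            raise SimConfigError(
                f"origin {int(bad)} outside [0, {self.genome_length})"
            )
        if self.nascent_halfwidth <= 0:
            raise SimConfigError("nascent_halfwidth must be positive")
        if self.nucleosome_spacing < self.footprint:
            raise SimConfigError(
                f"nucleosome_spacing ({self.nucleosome_spacing}) must be >= "
                f"footprint ({self.footprint})"
            )
        if self.frag_jitter < 0:
            raise SimConfigError("frag_jitter must be non-negative")
        if self.depth <= 0:
            raise SimConfigError("depth must be positive")
        if self.n_replicates < 1:
            raise SimConfigError("n_replicates must be >= 1")
        _check_nascent_overlap(ori, self.nascent_halfwidth, self.genome_length)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def _check_nascent_overlap(origins: np.ndarray, halfwidth: int, genome_length: int) -> None:
    starts = np.maximum(origins - halfwidth, 0)
    ends = np.minimum(origins + halfwidth, genome_length)
    for i in range(len(origins) - 1):
        if ends[i] > starts[i + 1]:
            raise SimConfigError(
                "nascent intervals overlap between origins "
                f"{int(origins[i])} and {int(origins[i + 1])}"
            )


def default_config(
    n_origins: int = 50,
    origin_spacing: int = 2_500_000,
    **overrides,
) -> SimConfig:
    """Evenly spaced origins on one chromosome; the standard study geometry."""
    origins = tuple(origin_spacing // 2 + k * origin_spacing for k in range(n_origins))
    genome_length = overrides.pop("genome_length", n_origins * origin_spacing)
    return SimConfig(genome_length=genome_length, origins=origins, **overrides)


# --------------------------------------------------------------------------
# layout
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome size, origin positions, and their nascent (BrdU) intervals."""

    chrom_name: str
    genome_length: int
    origins: np.ndarray  # (n,) int
    nascent_intervals: np.ndarray  # (n, 2) half-open [start, end)

    @property
    def n_origins(self) -> int:
        return len(self.origins)

    def in_nascent(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: does each position fall inside any nascent interval."""
        pos = np.asarray(positions)
        i = np.searchsorted(self.nascent_intervals[:, 0], pos, side="right") - 1
        ok = i >= 0
        res = np.zeros(pos.shape, dtype=bool)
        res[ok] = pos[ok] < self.nascent_intervals[i[ok], 1]
        return res


def build_layout(config: SimConfig) -> GenomeLayout:
    """Compute per-origin nascent intervals, clipped to the chromosome.

    Interval i is ``[origin_i - nascent_halfwidth, origin_i + nascent_halfwidth)``
    clipped to ``[0, genome_length)``; overlapping intervals raise
    :class:`SimConfigError` naming the two origins.
    """
    ori = np.asarray(config.origins, dtype=np.int64)
    _check_nascent_overlap(ori, config.nascent_halfwidth, config.genome_length)
    starts = np.maximum(ori - config.nascent_halfwidth, 0)
    ends = np.minimum(ori + config.nascent_halfwidth, config.genome_length)
    return GenomeLayout(
        chrom_name=config.chrom_name,
        genome_length=int(config.genome_length),
        origins=ori,
        nascent_intervals=np.stack([starts, ends], axis=1),
    )


# --------------------------------------------------------------------------
# replication
# --------------------------------------------------------------------------


@dataclass
class ChromatinState:
    """Ground-truth nucleosomes after replication of the nascent intervals.

    Parallel arrays; one entry per placed nucleosome.  Inside nascent
    intervals slots live on the two sister chromatids (a dyad may carry up to
    one nucleosome per sister); outside there is a single unreplicated duplex
    set, all parental-marked.
    """

    config: SimConfig
    layout: GenomeLayout
    dyad: np.ndarray  # int64
    daughter: np.ndarray  # int8: UNREPLICATED / LEADING / LAGGING
    mark: np.ndarray  # int8: PARENTAL / NEW
    origin_index: np.ndarray  # int32, -1 outside nascent intervals
    arm: np.ndarray  # int8: ARM_NONE / ARM_LEFT / ARM_RIGHT
    n_slots_per_origin: np.ndarray  # int64, pre-replication slots per origin

    @property
    def n(self) -> int:
        return len(self.dyad)

    @property
    def nascent(self) -> np.ndarray:
        return self.daughter != UNREPLICATED

    def nascent_strand_is_watson(self) -> np.ndarray:
        """Watson/Crick identity of each sister nucleosome's nascent strand.

        Right arm: the leading daughter's nascent strand runs 5'->3' with the
        fork, i.e. toward increasing coordinates, so it is Watson; the lagging
        daughter's is Crick.  Left arm: mirrored.  Undefined (False) for
        unreplicated nucleosomes.
        """
        return ((self.arm == ARM_RIGHT) & (self.daughter == LEADING)) | (
            (self.arm == ARM_LEFT) & (self.daughter == LAGGING)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dyad": self.dyad,
                "daughter": [DAUGHTER_NAMES[d] for d in self.daughter],
                "mark": [MARK_NAMES[m] for m in self.mark],
                "origin_index": self.origin_index,
                "arm": [ARM_NAMES[a] for a in self.arm],
            }
        )


def _slot_lattice(layout: GenomeLayout, config: SimConfig):
    """Dyad positions of all slots: (outside_dyads, per-origin nascent dyads)."""
    half = config.footprint // 2
    lo = half
    hi = layout.genome_length - (config.footprint - half)
    all_dyads = np.arange(lo, hi + 1, config.nucleosome_spacing, dtype=np.int64)
    outside = all_dyads[~layout.in_nascent(all_dyads)]

    nascent_dyads = []
    for i, (s, e) in enumerate(layout.nascent_intervals):
        o = layout.origins[i]
        kmin = -((o - max(s, lo)) // config.nucleosome_spacing)
        kmax = (min(e - 1, hi) - o) // config.nucleosome_spacing
        dy = o + np.arange(kmin, kmax + 1, dtype=np.int64) * config.nucleosome_spacing
        dy = dy[(dy >= s) & (dy < e) & (dy >= lo) & (dy <= hi)]
        nascent_dyads.append(dy)
    return outside, nascent_dyads


def simulate_replication(
    layout: GenomeLayout, config: SimConfig, seed: int | list[int] | None = None
) -> ChromatinState:
    """Replicate the nascent intervals and place nucleosomes on both sisters.

    Per nascent slot, independently: the pre-replication parental nucleosome
    is retained with probability ``p_retain`` and placed (same dyad) on the
    leading daughter with probability ``p_lead``, else the lagging daughter;
    otherwise it is discarded.  Each empty sister slot is then filled with a
    new-marked nucleosome with probability ``new_fill``.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    outside, nascent_dyads = _slot_lattice(layout, config)

    dyads = [outside]
    daughters = [np.full(len(outside), UNREPLICATED, dtype=np.int8)]
    marks = [np.full(len(outside), PARENTAL, dtype=np.int8)]
    origin_idx = [np.full(len(outside), -1, dtype=np.int32)]
    arms = [np.full(len(outside), ARM_NONE, dtype=np.int8)]

    n_slots = np.array([len(d) for d in nascent_dyads], dtype=np.int64)
    for i, dy in enumerate(nascent_dyads):
        n = len(dy)
        retained = rng.random(n) < config.p_retain
        to_leading = rng.random(n) < config.p_lead
        # parental nucleosomes on their chosen sister
        par_daughter = np.where(to_leading, LEADING, LAGGING).astype(np.int8)
        # empty sister slots: the opposite sister where retained, both where lost
        fill_leading = (~retained) | (par_daughter == LAGGING)
        fill_lagging = (~retained) | (par_daughter == LEADING)
        new_leading = fill_leading & (rng.random(n) < config.new_fill)
        new_lagging = fill_lagging & (rng.random(n) < config.new_fill)

        o = layout.origins[i]
        arm = np.where(dy < o, ARM_LEFT, ARM_RIGHT).astype(np.int8)

        for sel, daught, mk in (
            (retained, par_daughter, PARENTAL),
            (new_leading, np.full(n, LEADING, dtype=np.int8), NEW),
            (new_lagging, np.full(n, LAGGING, dtype=np.int8), NEW),
        ):
            k = int(sel.sum())
            if k == 0:
                continue
            dyads.append(dy[sel])
            daughters.append(np.asarray(daught)[sel] if np.ndim(daught) else daught)
            marks.append(np.full(k, mk, dtype=np.int8))
            origin_idx.append(np.full(k, i, dtype=np.int32))
            arms.append(arm[sel])

    return ChromatinState(
        config=config,
        layout=layout,
        dyad=np.concatenate(dyads),
        daughter=np.concatenate(daughters),
        mark=np.concatenate(marks),
        origin_index=np.concatenate(origin_idx),
        arm=np.concatenate(arms),
        n_slots_per_origin=n_slots,
    )


def truth_summary(state: ChromatinState) -> pd.DataFrame:
    """Per-origin retained-parental counts and leading fraction.

    ``leading_fraction`` is NaN (undefined), not 0, for origins without any
    retained parental nucleosome.
    """
    n_ori = state.layout.n_origins
    nascent_par = state.nascent & (state.mark == PARENTAL)
    idx = state.origin_index[nascent_par]
    lead = state.daughter[nascent_par] == LEADING
    n_retained = np.bincount(idx, minlength=n_ori).astype(np.int64)
    n_leading = np.bincount(idx[lead], minlength=n_ori).astype(np.int64)
    n_lagging = n_retained - n_leading
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_retained > 0, n_leading / np.maximum(n_retained, 1), np.nan)
    return pd.DataFrame(
        {
            "origin_index": np.arange(n_ori),
            "origin_pos": state.layout.origins,
            "n_slots": state.n_slots_per_origin,
            "n_retained": n_retained,
            "n_leading": n_leading,
            "n_lagging": n_lagging,
            "leading_fraction": frac,
        }
    )


# --------------------------------------------------------------------------
# read generation
# --------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Strand-tagged sequenced fragments from one sample of one replicate."""

    chrom: str
    start: np.ndarray  # int64, 0-based
    end: np.ndarray  # int64, half-open
    watson: np.ndarray  # bool; False = Crick
    sample: str
    replicate: int = 0
    drops: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "strand": np.where(self.watson, "watson", "crick"),
                "sample": self.sample,
                "replicate": self.replicate,
            }
        )


def _capture_weights(state: ChromatinState, sample: str) -> np.ndarray:
    """Relative pulldown weight of every nucleosome in the given sample kind."""
    cfg = state.config
    ones = np.ones(state.n)
    if sample == "input":
        return ones
    if sample == "mnase_brdu_ip":
        return np.where(state.nascent, 1.0, cfg.brdu_leakage)
    if sample in ("chip_parental", "chip_new", "espan_parental", "espan_new"):
        target = PARENTAL if sample.endswith("parental") else NEW
        w = np.where(state.mark == target, 1.0, cfg.chip_offtarget)
        if sample.startswith("espan"):
            w = w * np.where(state.nascent, 1.0, cfg.brdu_leakage)
        return w
    raise ValueError(f"unknown sample kind {sample!r}; expected one of {SAMPLE_KINDS}")


def generate_reads(
    state: ChromatinState,
    sample: str,
    depth: int | None = None,
    seed: int | None = None,
    replicate: int = 0,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Sample nucleosome-footprint reads with replacement for one sample kind.

    The read count is Poisson(``depth``).  Reads span ``dyad +- footprint/2``
    with Gaussian end jitter of s.d. ``frag_jitter``.  Strand: samples that
    went through BrdU-IP read out the nascent strand of sister nucleosomes
    (leakage reads from unreplicated chromatin are strand-balanced); all other
    samples are strand-balanced Watson/Crick.
    """
    cfg = state.config
    w = _capture_weights(state, sample)
    total = w.sum()
    if state.n == 0 or total <= 0:
        raise EmptySampleError(f"no eligible nucleosomes for sample kind {sample!r}")
    if rng is None:
        base = cfg.seed if seed is None else seed
        rng = np.random.default_rng([base, _SAMPLE_CODE[sample], replicate])
    n_reads = int(rng.poisson(cfg.depth if depth is None else depth))

    idx = rng.choice(state.n, size=n_reads, p=w / total)
    half = cfg.footprint // 2
    start = state.dyad[idx] - half
    end = state.dyad[idx] + (cfg.footprint - half)
    if cfg.frag_jitter > 0:
        start = start + np.rint(rng.normal(0, cfg.frag_jitter, n_reads)).astype(np.int64)
        end = end + np.rint(rng.normal(0, cfg.frag_jitter, n_reads)).astype(np.int64)
    start = np.clip(start, 0, state.layout.genome_length - 1)
    end = np.clip(np.maximum(end, start + 1), 1, state.layout.genome_length)

    if sample in BRDU_SAMPLES:
        nascent = state.nascent[idx]
        watson = np.where(
            nascent,
            state.nascent_strand_is_watson()[idx],
            rng.random(n_reads) < 0.5,
        )
    else:
        watson = rng.random(n_reads) < 0.5

    return ReadSet(
        chrom=state.layout.chrom_name,
        start=start.astype(np.int64),
        end=end.astype(np.int64),
        watson=np.asarray(watson, dtype=bool),
        sample=sample,
        replicate=replicate,
    )


# --------------------------------------------------------------------------
# SAM export
# --------------------------------------------------------------------------

_READ_LEN = 50  # nominal sequenced length of each mate in paired mode


def write_sam(reads: ReadSet, layout: GenomeLayout, path: str, paired: bool = True) -> None:
    """Write reads to a coordinate-sorted SAM file.

    Paired mode emits proper pairs whose first-in-pair orientation encodes the
    strand (Watson -> first-in-pair forward, FLAG 99/147; Crick -> FLAG
    83/163) with the mate fabricated at the opposite fragment end.  Unpaired
    mode emits one record spanning the whole fragment with the reverse-strand
    bit encoding Crick (FLAG 16).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": layout.chrom_name, "LN": int(layout.genome_length)}],
    }
    order = np.argsort(reads.start, kind="stable")
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i in order:
            start = int(reads.start[i])
            end = int(reads.end[i])
            frag = end - start
            watson = bool(reads.watson[i])
            qname = f"{reads.sample}.{reads.replicate}.{i}"
            if not paired:
                a = pysam.AlignedSegment(out.header)
                a.query_name = qname
                a.flag = 0 if watson else 16
                a.reference_id = 0
                a.reference_start = start
                a.mapping_quality = 60
                a.cigarstring = f"{frag}M"
                a.query_sequence = "A" * frag
                out.write(a)
                continue
            rlen = min(_READ_LEN, frag)
            pos1, pos2 = start, end - rlen
            if watson:
                f1, f2 = 99, 147  # r1 forward at the left end
                p1, p2, t1 = pos1, pos2, frag
            else:
                f1, f2 = 83, 163  # r1 reverse at the right end
                p1, p2, t1 = pos2, pos1, -frag
            for fl, p, pn, tl, r in ((f1, p1, p2, t1, 1), (f2, p2, p1, -t1, 2)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = qname
                a.flag = fl
                a.reference_id = 0
                a.reference_start = p
                a.mapping_quality = 60
                a.cigarstring = f"{rlen}M"
                a.query_sequence = "A" * rlen
                a.next_reference_id = 0
                a.next_reference_start = pn
                a.template_length = tl
                out.write(a)
    logger.info("wrote %d reads (%s) to %s", reads.n, "paired" if paired else "single", path)
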