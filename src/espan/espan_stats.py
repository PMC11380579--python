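"""Core eSPAN strand-bias statistics.

The analysis quantifies, per genomic bin, how nascent-chromatin ChIP signal
partitions between the two reference strands after normalization for nascent
DNA abundance:

* normalized density  ``D(s, b) = (CPM_espan(s, b) + c) / (CPM_brdu(s, b) + c)``
  per strand s (Watson/Crick), with pseudocount c and a validity mask
  (insufficient BrdU coverage, or outside called BrdU regions);
* eSPAN bias          ``bias(b) = log2(D(Watson, b) / D(Crick, b))``;
* origin-centered metaprofiles with the replicate confidence rule
  (average across origins within each replicate, then mean +- 2 SE across
  replicates);
* per-origin arm summaries: left/right-arm mean bias and the leading-bias
  score ``(right - left) / 2`` whose sign is positive when the signal is
  enriched on nascent leading strands;
* leading/lagging density summaries (Watson counts as leading on the right
  arm and lagging on the left arm; Crick the reverse) and between-condition
  comparisons (percent change of condition means, Welch t-test, optional
  rank-sum).

The rank-sum test used for arm comparisons has an exact small-sample path
(full enumeration of rank splits) and a tie- and continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .enrich_call import EnrichedRegion
from .strand_io import OriginSet, StrandCoverage

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# normalized density and bias
# --------------------------------------------------------------------------


@dataclass
class NormalizedDensity:
    """BrdU-normalized per-bin strand densities for one eSPAN replicate."""

    chrom: str
    chrom_length: int
    bin_width: int
    dens_watson: np.ndarray  # float, per bin
    dens_crick: np.ndarray
    mask: np.ndarray  # bool, True = bin is valid
    sample: str = "unknown"
    replicate: int = 0
    pseudocount: float = 0.05
    min_brdu: int = 5

    @property
    def n_bins(self) -> int:
        return len(self.dens_watson)

    def swapped(self) -> "NormalizedDensity":
        """Watson/Crick relabeling (used by antisymmetry checks)."""
        return NormalizedDensity(
            chrom=self.chrom,
            chrom_length=self.chrom_length,
            bin_width=self.bin_width,
            dens_watson=self.dens_crick.copy(),
            dens_crick=self.dens_watson.copy(),
            mask=self.mask.copy(),
            sample=self.sample,
            replicate=self.replicate,
            pseudocount=self.pseudocount,
            min_brdu=self.min_brdu,
        )


@dataclass
class BiasProfile:
    """Per-bin log2(Watson/Crick) normalized eSPAN bias with validity mask."""

    chrom: str
    chrom_length: int
    bin_width: int
    bias: np.ndarray  # float, NaN where masked
    mask: np.ndarray  # bool, True = valid
    sample: str = "unknown"
    replicate: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.bias)


def _region_mask(regions, n_bins: int, bin_width: int) -> np.ndarray:
    mask = np.zeros(n_bins, dtype=bool)
    for r in regions:
        a = max(r.start // bin_width, 0)
        b = min(-(-r.end // bin_width), n_bins)
        mask[a:b] = True
    return mask


def normalize_density(
    espan: StrandCoverage,
    brdu: StrandCoverage,
    pseudocount: float = 0.05,
    min_brdu: int = 5,
    regions: list[EnrichedRegion] | None = None,
) -> NormalizedDensity:
    """Per-strand eSPAN density normalized by MNase-BrdU-IP coverage.

    Both coverages are converted to CPM; the density is their pseudocounted
    ratio.  Bins with pooled raw BrdU count below ``min_brdu`` are masked, as
    are bins outside the supplied BrdU-enriched regions (when given).
    """
    if espan.bin_width != brdu.bin_width or espan.n_bins != brdu.n_bins:
        raise ValueError("eSPAN and BrdU coverage must share binning")
    if espan.library_size == 0 or brdu.library_size == 0:
        raise ValueError("both library sizes must be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    dens = {}
    for strand in ("watson", "crick"):
        dens[strand] = (espan.cpm(strand) + pseudocount) / (brdu.cpm(strand) + pseudocount)
    mask = brdu.pooled() >= min_brdu
    if regions is not None:
        mask &= _region_mask(regions, espan.n_bins, espan.bin_width)
    return NormalizedDensity(
        chrom=espan.chrom,
        chrom_length=espan.chrom_length,
        bin_width=espan.bin_width,
        dens_watson=dens["watson"],
        dens_crick=dens["crick"],
        mask=mask,
        sample=espan.sample,
        replicate=espan.replicate,
        pseudocount=pseudocount,
        min_brdu=min_brdu,
    )


def compute_bias(dens: NormalizedDensity) -> BiasProfile:
    """log2 ratio of normalized Watson to normalized Crick density.

    Antisymmetric under strand relabeling; finite on unmasked bins because the
    pseudocount keeps both densities positive.
    """
    bias = np.full(dens.n_bins, np.nan)
    m = dens.mask
    bias[m] = np.log2(dens.dens_watson[m] / dens.dens_crick[m])
    return BiasProfile(
        chrom=dens.chrom,
        chrom_length=dens.chrom_length,
        bin_width=dens.bin_width,
        bias=bias,
        mask=m.copy(),
        sample=dens.sample,
        replicate=dens.replicate,
    )


# --------------------------------------------------------------------------
# origin-relative windows
# --------------------------------------------------------------------------


def _quiet_nan(fn, *args, **kwargs):
    """Run a nan-aware reduction without all-NaN slice warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return fn(*args, **kwargs)


def _origin_positions(origins, chrom: str) -> np.ndarray:
    if isinstance(origins, OriginSet):
        return origins.for_chrom(chrom)
    return np.asarray(origins, dtype=np.int64)


def _window_matrix(profile: BiasProfile, positions: np.ndarray, window_bp: int) -> np.ndarray:
    """Origin x relative-bin matrix of bias values (NaN outside mask/genome).

    Column j covers origin-relative offsets ``[(j - K) * bw, (j - K + 1) * bw)``
    where ``K = window_bp // bw``; the bin containing the origin point starts
    the right arm (half-open convention).
    """
    bw = profile.bin_width
    K = window_bp // bw
    n_cols = 2 * K
    mat = np.full((len(positions), n_cols), np.nan)
    for i, pos in enumerate(positions):
        c = int(pos) // bw
        a, b = c - K, c + K
        lo, hi = max(a, 0), min(b, profile.n_bins)
        if lo < hi:
            mat[i, lo - a : hi - a] = profile.bias[lo:hi]
    return mat


@dataclass
class MetaProfile:
    """Origin-averaged bias by origin-relative position, with replicate CI."""

    rel_pos: np.ndarray  # bp offset of each column's bin start from the origin bin
    per_replicate: np.ndarray  # (R, n_pos) per-replicate origin-averaged bias
    mean: np.ndarray  # across-replicate mean
    se: np.ndarray  # across-replicate standard error (NaN when R == 1)
    ci_low: np.ndarray  # mean - 2 SE
    ci_high: np.ndarray  # mean + 2 SE
    n_origins: np.ndarray  # (R, n_pos) unmasked origin count behind each value

    @property
    def n_replicates(self) -> int:
        return self.per_replicate.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"rel_pos": self.rel_pos, "mean": self.mean, "se": self.se,
                           "ci_low": self.ci_low, "ci_high": self.ci_high})
        for r in range(self.n_replicates):
            df[f"replicate_{r + 1}"] = self.per_replicate[r]
        return df


def origin_metaprofile(
    profiles: list[BiasProfile],
    origins,
    window_bp: int = 5000,
    single_rep_se: str = "none",
) -> MetaProfile:
    """Origin-centered bias metaprofile with the replicate confidence rule.

    Within each replicate, bias values are placed on origin-relative
    coordinates and averaged across origins per position (masked bins
    excluded).  Across replicates, mean and SE = s/sqrt(R) give the ribbon
    ``mean +- 2 SE``; a single replicate yields an undefined (NaN) ribbon
    unless ``single_rep_se='origins'``, which substitutes the across-origin
    standard error (a different, within-replicate notion of uncertainty —
    labeled as such in the run log and TSV headers).  Positions with no
    unmasked data in any replicate stay NaN rather than being fabricated.
    """
    if single_rep_se not in ("none", "origins"):
        raise ValueError("single_rep_se must be 'none' or 'origins'")
    if not profiles:
        raise ValueError("at least one replicate profile is required")
    bw = profiles[0].bin_width
    if window_bp % bw != 0:
        raise ValueError(f"window_bp ({window_bp}) must be a multiple of bin_width ({bw})")
    K = window_bp // bw
    rel_pos = (np.arange(2 * K) - K) * bw
    per_rep = []
    n_orig = []
    origin_se = None
    for prof in profiles:
        if prof.bin_width != bw:
            raise ValueError("replicate profiles must share bin_width")
        positions = _origin_positions(origins, prof.chrom)
        mat = _window_matrix(prof, positions, window_bp)
        per_rep.append(_quiet_nan(np.nanmean, mat, axis=0))
        n_orig.append(np.sum(~np.isnan(mat), axis=0))
        if len(profiles) == 1 and single_rep_se == "origins":
            n_ok = np.maximum(np.sum(~np.isnan(mat), axis=0), 1)
            origin_se = _quiet_nan(np.nanstd, mat, axis=0, ddof=1) / np.sqrt(n_ok)
    per_rep = np.asarray(per_rep)
    n_orig = np.asarray(n_orig)
    R = per_rep.shape[0]
    mean = _quiet_nan(np.nanmean, per_rep, axis=0)
    if R >= 2:
        se = _quiet_nan(np.nanstd, per_rep, axis=0, ddof=1) / math.sqrt(R)
    elif origin_se is not None:
        se = origin_se
        logger.warning("single replicate: ribbon uses the across-origin SE")
    else:
        se = np.full_like(mean, np.nan)
        logger.warning("single replicate: metaprofile confidence ribbon undefined")
    return MetaProfile(
        rel_pos=rel_pos,
        per_replicate=per_rep,
        mean=mean,
        se=se,
        ci_low=mean - 2 * se,
        ci_high=mean + 2 * se,
        n_origins=n_orig,
    )


def arm_bias_summary(
    bias: BiasProfile,
    origins,
    window_bp: int = 5000,
) -> pd.DataFrame:
    """Per-origin left/right-arm mean bias and leading-bias score.

    Left arm: bins in ``[origin - window_bp, origin)``; right arm:
    ``[origin, origin + window_bp)`` (the bin containing the origin point
    belongs to the right arm).  ``leading_bias_score = (right - left) / 2``;
    positive when the signal is enriched on nascent leading strands.  Origins
    with an all-masked arm are excluded; the count is in
    ``df.attrs["n_excluded"]``.
    """
    if window_bp < bias.bin_width:
        raise ValueError("window_bp must be >= bin_width")
    positions = _origin_positions(origins, bias.chrom)
    bw = bias.bin_width
    K = window_bp // bw
    rows = []
    n_excluded = 0
    for i, pos in enumerate(positions):
        c = int(pos) // bw
        left = bias.bias[max(c - K, 0) : c]
        right = bias.bias[c : min(c + K, bias.n_bins)]
        n_left = int(np.sum(~np.isnan(left)))
        n_right = int(np.sum(~np.isnan(right)))
        if n_left == 0 or n_right == 0:
            n_excluded += 1
            continue
        lm = float(np.nanmean(left))
        rm = float(np.nanmean(right))
        rows.append(
            {
                "origin_index": i,
                "origin_pos": int(pos),
                "left_mean_bias": lm,
                "right_mean_bias": rm,
                "leading_bias_score": (rm - lm) / 2.0,
                "n_left": n_left,
                "n_right": n_right,
            }
        )
    if n_excluded:
        logger.warning("%d origins excluded (all-masked arm)", n_excluded)
    df = pd.DataFrame(
        rows,
        columns=[
            "origin_index", "origin_pos", "left_mean_bias", "right_mean_bias",
            "leading_bias_score", "n_left", "n_right",
        ],
    )
    df.attrs["n_excluded"] = n_excluded
    return df


def bias_at_dyads(bias: BiasProfile, nucleosomes) -> pd.DataFrame:
    """Nucleosome-level bias readout: the bias value at each called dyad.

    Maps every :class:`~espan.enrich_call.NucleosomeCall` onto the bin
    containing its dyad; dyads in masked or out-of-range bins get NaN.
    Provided as the nucleosome-resolution alternative to the per-bin bias
    track.
    """
    dyads = np.asarray([n.dyad for n in nucleosomes], dtype=np.int64)
    occ = np.asarray([n.occupancy for n in nucleosomes], dtype=float)
    bins = dyads // bias.bin_width
    ok = (bins >= 0) & (bins < bias.n_bins)
    vals = np.full(len(dyads), np.nan)
    vals[ok] = bias.bias[bins[ok]]
    return pd.DataFrame({"dyad": dyads, "occupancy": occ, "bias": vals})


# --------------------------------------------------------------------------
# rank-sum test
# --------------------------------------------------------------------------

_EXACT_LIMIT = 12  # combined size up to which the exact null is enumerated


def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of the first sample (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def wilcoxon_arm_test(left: np.ndarray, right: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null by full enumeration of rank splits when the combined sample is
    small (n + m <= 12) and tie-free; otherwise the normal approximation with
    tie correction and continuity correction.  Returns (U of the first
    sample, two-sided p).  If every value in both samples is identical the
    test is degenerate and p = 1 by convention.
    """
    x = np.asarray(left, dtype=float)
    y = np.asarray(right, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    u = _rank_sum_u(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.warning("rank-sum test degenerate: all values identical; p = 1")
        return u, 1.0
    n, m = len(x), len(y)
    has_ties = len(np.unique(pooled)) < n + m
    if n + m <= _EXACT_LIMIT and not has_ties:
        return u, _exact_two_sided_p(u, n, m)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return u, float(res.pvalue)


def _exact_two_sided_p(u_obs: float, n: int, m: int) -> float:
    """Exact two-sided p by enumerating all C(n+m, n) rank assignments."""
    total = n + m
    ranks = np.arange(1, total + 1)
    offset = n * (n + 1) / 2.0
    us = np.fromiter(
        (sum(ranks[list(c)]) - offset for c in combinations(range(total), n)),
        dtype=float,
    )
    n_le = np.sum(us <= u_obs)
    n_ge = np.sum(us >= u_obs)
    return float(min(1.0, 2.0 * min(n_le, n_ge) / len(us)))


# --------------------------------------------------------------------------
# leading/lagging densities and condition comparison
# --------------------------------------------------------------------------


def strand_density_summary(
    dens_list: list[NormalizedDensity],
    origins,
    window_bp: int = 2500,
) -> pd.DataFrame:
    """Per-origin mean leading/lagging normalized densities around origins.

    Per bin, the Watson density counts toward the leading strand on the right
    arm and the lagging strand on the left arm; Crick the reverse (fork
    geometry).  Means are over unmasked bins within ``+-window_bp``; replicate
    values are averaged per origin.  Origins with an all-masked window in
    every replicate are excluded (count in ``df.attrs["n_excluded"]``).
    """
    if not dens_list:
        raise ValueError("at least one replicate is required")
    chrom = dens_list[0].chrom
    positions = _origin_positions(origins, chrom)
    bw = dens_list[0].bin_width
    K = window_bp // bw
    if K < 1:
        raise ValueError("window_bp must be >= bin_width")
    lead_acc = np.full((len(dens_list), len(positions)), np.nan)
    lag_acc = np.full((len(dens_list), len(positions)), np.nan)
    for r, dens in enumerate(dens_list):
        dw = np.where(dens.mask, dens.dens_watson, np.nan)
        dc = np.where(dens.mask, dens.dens_crick, np.nan)
        for i, pos in enumerate(positions):
            c = int(pos) // bw
            lo, hi = max(c - K, 0), min(c + K, dens.n_bins)
            leading = np.concatenate([dw[c:hi], dc[lo:c]])  # right-arm W, left-arm C
            lagging = np.concatenate([dc[c:hi], dw[lo:c]])
            if np.any(~np.isnan(leading)):
                lead_acc[r, i] = np.nanmean(leading)
                lag_acc[r, i] = np.nanmean(lagging)
    lead = _quiet_nan(np.nanmean, lead_acc, axis=0)
    lag = _quiet_nan(np.nanmean, lag_acc, axis=0)
    ok = ~np.isnan(lead)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("%d origins excluded from density summary (all-masked)", n_excluded)
    df = pd.DataFrame(
        {
            "origin_index": np.arange(len(positions))[ok],
            "origin_pos": positions[ok],
            "leading_density": lead[ok],
            "lagging_density": lag[ok],
        }
    )
    df.attrs["n_excluded"] = n_excluded
    return df


def compare_conditions(
    wt: pd.DataFrame,
    mut: pd.DataFrame,
    rank_sum: bool = True,
) -> pd.DataFrame:
    """Percent change of per-origin densities between two conditions.

    One row per strand (leading, lagging): condition means, percent change
    ``100 * (mut - wt) / wt``, Welch (unequal-variance) two-tailed t-test and,
    optionally, the rank-sum p.
    """
    rows = []
    for strand in ("leading", "lagging"):
        col = f"{strand}_density"
        a = np.asarray(wt[col], dtype=float)
        b = np.asarray(mut[col], dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 origins per condition")
        wt_mean = float(a.mean())
        mut_mean = float(b.mean())
        if wt_mean == 0:
            raise ValueError(f"wild-type mean {strand} density is 0; percent change undefined")
        t, p = stats.ttest_ind(b, a, equal_var=False)
        row = {
            "strand": strand,
            "wt_mean": wt_mean,
            "mut_mean": mut_mean,
            "percent_change": 100.0 * (mut_mean - wt_mean) / wt_mean,
            "t_statistic": float(t),
            "p_value": float(p),
        }
        if rank_sum:
            _, rp = wilcoxon_arm_test(b, a)
            row["rank_sum_p"] = rp
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# heatmap
# --------------------------------------------------------------------------


def heatmap_matrix(
    bias: BiasProfile,
    origins,
    window_bp: int = 5000,
    sort_mode: str = "genomic",
) -> pd.DataFrame:
    """Origin x origin-relative-position bias matrix (NaN = masked).

    ``sort_mode='genomic'`` keeps genomic order; ``'score'`` sorts rows by
    descending leading-bias score (computed over the same window).
    """
    if sort_mode not in ("genomic", "score"):
        raise ValueError("sort_mode must be 'genomic' or 'score'")
    positions = _origin_positions(origins, bias.chrom)
    mat = _window_matrix(bias, positions, window_bp)
    bw = bias.bin_width
    K = window_bp // bw
    cols = (np.arange(2 * K) - K) * bw
    df = pd.DataFrame(mat, columns=cols)
    df.index = [f"origin_{i}" for i in range(len(positions))]
    if sort_mode == "score":
        left = _quiet_nan(np.nanmean, mat[:, :K], axis=1)
        right = _quiet_nan(np.nanmean, mat[:, K:], axis=1)
        score = (right - left) / 2.0
        order = np.argsort(-np.where(np.isnan(score), -np.inf, score), kind="stable")
        df = df.iloc[order]
    return df


# --------------------------------------------------------------------------
# figures
# --------------------------------------------------------------------------


def plot_metaprofile(mp: MetaProfile, path: str, title: str = "") -> None:
    """Bias line plot with the mean +- 2 SE ribbon."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bw = float(mp.rel_pos[1] - mp.rel_pos[0]) if len(mp.rel_pos) > 1 else 1.0
    x = (mp.rel_pos + bw / 2) / 1000.0
    fig, ax = plt.subplots(figsize=(5, 3.2))
    if mp.n_replicates >= 2 and np.any(np.isfinite(mp.se)):
        ax.fill_between(x, mp.ci_low, mp.ci_high, alpha=0.3, lw=0, label="mean ± 2 SE")
    ax.plot(x, mp.mean, lw=1.5)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5, ls=":")
    ax.set_xlabel("distance from origin (kb)")
    ax.set_ylabel("eSPAN bias  log2(W/C)")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(matrix: pd.DataFrame, path: str, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 5))
    vmax = np.nanmax(np.abs(matrix.values)) or 1.0
    im = ax.imshow(matrix.values, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   extent=[matrix.columns[0] / 1000, matrix.columns[-1] / 1000, len(matrix), 0])
    fig.colorbar(im, ax=ax, label="eSPAN bias log2(W/C)")
    ax.set_xlabel("distance from origin (kb)")
    ax.set_ylabel("origin")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_density_violin(wt: pd.DataFrame, mut: pd.DataFrame, path: str,
                        labels: tuple[str, str] = ("wt", "mut")) -> None:
    """Leading/lagging per-origin density distributions for two conditions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    data = [wt["leading_density"], mut["leading_density"],
            wt["lagging_density"], mut["lagging_density"]]
    ax.violinplot([np.asarray(d, dtype=float) for d in data], showmeans=True)
    ax.set_xticks([1, 2, 3, 4])
    ax.set_xticklabels([f"lead {labels[0]}", f"lead {labels[1]}",
                        f"lag {labels[0]}", f"lag {labels[1]}"], fontsize=8)
    ax.set_ylabel("normalized eSPAN density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
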