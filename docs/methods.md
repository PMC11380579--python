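# Methods

This note documents the generative model behind the simulator, the
statistical definitions used by the pipeline, the parameter defaults and the
reasoning behind them, the numerical edge-case rules, and the limits of what
the validation scenarios can show about real data.

## 1. Generative model of the experiment

One synthetic chromosome carries a lattice of nucleosome slots, one dyad
every `nucleosome_spacing` (165 bp, the canonical budding-yeast repeat); each
nucleosome protects a `footprint` of 147 bp.  Replication initiates
bidirectionally at point origins; the 40-minute labeling pulse is modeled as
a fixed nascent interval of `± nascent_halfwidth` (10 kb) per origin, since
only origin-relative behavior enters the statistics.  Inside a nascent
interval the slot lattice is re-anchored at the origin and duplicated onto
two sister chromatids; outside, a single unreplicated duplex remains, fully
parental-marked (old histones genome-wide carry the parental-mark surrogate).

Per nascent slot, independently:

1. the pre-replication parental nucleosome is **retained** with probability
   `p_retain`, landing on the leading-strand daughter with probability
   `p_lead`, else the lagging-strand daughter; otherwise it is lost;
2. every still-empty sister slot is filled by a **new-marked** nucleosome
   with probability `new_fill`.

"Leading daughter" at a locus means the chromatid whose nascent strand was
synthesized continuously there.  Fork geometry fixes the strand readout: on
the right arm of an origin the leading daughter's nascent strand runs 5'→3'
with the fork, i.e. toward increasing coordinates, and is therefore the
Watson strand; on the left arm the assignment mirrors.  This single rule
generates the sign conventions used throughout (positive leading-bias score
⇔ leading-strand enrichment).

### Read sampling

Each sample kind draws `Poisson(depth)` nucleosome-footprint reads with
replacement, with per-nucleosome capture weights that factorize into an
antibody term and a BrdU-IP term:

| sample            | antibody weight                  | BrdU-IP weight                 | strand |
|-------------------|----------------------------------|--------------------------------|--------|
| input             | 1                                | 1                              | ½ / ½  |
| chip_parental/new | 1 target, `chip_offtarget` other | 1                              | ½ / ½  |
| mnase_brdu_ip     | 1                                | 1 nascent, `brdu_leakage` else | nascent strand; leakage ½ / ½ |
| espan_parental/new| as ChIP                          | as BrdU-IP                     | nascent strand; leakage ½ / ½ |

Fragment ends are jittered by Gaussian noise (`frag_jitter` = 10 bp s.d.).

The BrdU-IP **leakage** term deserves emphasis, because it is what makes
between-strain density comparisons meaningful at all.  Densities are computed
from library-size-normalized counts (CPM), and the per-bin CPM of a
homogeneous read population is invariant to uniform changes in the
population's size: if eSPAN libraries contained only nascent target
nucleosomes, reducing parental retention uniformly would leave every
normalized density unchanged, and no retention phenotype could ever be
detected.  Real single-stranded eSPAN libraries carry a genome-wide
background of mature chromatin that leaks through the BrdU pulldown — for
the parental mark this background is large, because the ChIP itself pulls
the entire (parental-marked) genome and the BrdU-IP only enriches, not
purifies.  That background is spatially flat and strand-balanced, so it does
not distort origin-proximal bias profiles, but it anchors the library size:
when nascent parental occupancy drops by a factor r, the origin-proximal
share of the library — hence the normalized density — drops by ≈ r.  The
default geometry keeps the nascent fraction of the chromosome small (20 kb
of every 2.5 Mb), putting the parental eSPAN library in this
background-dominated regime (~97% background).  The residual mapping error
from finite background dominance, in-bin off-target contamination, and the
pseudocount is ≈ +2 percentage points at r = 0.65 (a true −35% is read out
as ≈ −33%).

Consequence: reads in BrdU-containing samples are *mostly* from nascent
intervals but not exclusively; the strict "every eSPAN read intersects a
nascent interval" property holds exactly only at `brdu_leakage = 0` (and is
tested there).

### Defaults

| parameter            | default   | unit | rationale |
|----------------------|-----------|------|-----------|
| `nucleosome_spacing` | 165       | bp   | yeast nucleosome repeat length |
| `footprint`          | 147       | bp   | nucleosome-protected DNA |
| `nascent_halfwidth`  | 10 000    | bp   | fork extent per side in a 40-min pulse; only origin-relative behavior matters |
| origin spacing       | 2 500 000 | bp   | sparse early-firing origins; keeps nascent DNA a small genome fraction (background-dominated libraries, see above) |
| `p_retain`           | 0.9       | —    | high but incomplete parental recycling in a reference strain |
| `p_lead`             | 0.5       | —    | symmetric transfer (wild-type-like) |
| `new_fill`           | 1.0       | —    | nascent chromatin is refilled to full nucleosome density; makes total sister occupancy independent of retention |
| `chip_offtarget`     | 0.005     | —    | per-nucleosome relative pulldown of the wrong mark (good antibody) |
| `brdu_leakage`       | 0.25      | —    | per-nucleosome relative capture of non-nascent chromatin in BrdU-IP (≈4× enrichment) |
| `frag_jitter`        | 10        | bp   | MNase/library end heterogeneity |
| `depth`              | 500 000   | reads/sample | resolves per-bin strand counts at the default binning |
| `n_replicates`       | 2         | —    | two biological replicates, the usual design |

Biological replicates re-run both chromatin replication (independent
parental placements) and sequencing.

## 2. Pipeline definitions

* **Strand assignment.**  A fragment is Watson when its first-in-pair (or
  single-end) read aligned forward; Crick when flag bit 0x10 is set.
  Second-in-pair flags never define strand.  For proper pairs the counted
  unit is the full fragment span (position + template length); unmapped,
  secondary, supplementary, low-MAPQ (< 20 by default) and cross-reference
  pairs are dropped and counted.  No duplicate removal.
* **Binning.**  Midpoint rule by default: one count to the bin containing
  `floor((start+end)/2)`, bins half-open tiling `[0, L)`.  Under this rule
  per-strand counts sum exactly to the number of retained fragments.  A
  full-overlap `spread` mode exists for track export.
* **Normalized density.**  `D(s,b) = (CPM_e(s,b)+c) / (CPM_b(s,b)+c)` with
  pseudocount `c = 0.05` CPM.  Bins with pooled raw BrdU counts below
  `min_brdu = 5` are masked, as are bins outside called BrdU regions when
  region filtering is enabled.  The pseudocount is deliberately small
  relative to a typical origin-proximal signal bin (several CPM): a larger
  value shrinks genuine ratios toward 1 and visibly biases percent-change
  estimates between strains; the masking rule, not the pseudocount, is the
  guard against empty denominators.
* **Bias.** `log2(D_W / D_C)` per unmasked bin, NaN elsewhere; exactly
  antisymmetric under strand relabeling.
* **Metaprofile.**  Bias values are placed on origin-relative coordinates,
  averaged across origins within each replicate, then mean ± 2·SE across
  replicates per position (SE = s/√R).  R = 1 gives an undefined ribbon by
  default; an across-origin SE mode exists for single-replicate data and is
  labeled as such.  Positions with no unmasked data are flagged NaN, never
  interpolated.
* **Arms.**  Left arm `[origin − w, origin)`, right arm `[origin, origin + w)`
  — the bin containing the origin point belongs to the right arm (half-open
  convention); no origin-proximal exclusion zone.  Default window ±5 kb for
  bias summaries, ±2.5 kb for density summaries.  Origins with an all-masked
  arm are excluded and counted.
* **Rank-sum test.**  Exact two-sided p by full enumeration of rank splits
  when n + m ≤ 12 without ties; otherwise the normal approximation with
  midranks, tie correction and continuity correction.  All-identical input
  degenerates to p = 1 with a warning.
* **Condition comparison.**  Per strand: percent change of condition means,
  Welch (unequal-variance) two-tailed t-test, optional rank-sum p.  Zero
  wild-type mean is an error, not a −100% readout.
* **Origin weighting.**  Metaprofiles and arm statistics weight origins
  equally, not by read count; with equal-size simulated origins the two
  coincide, for real data this is a documented choice.
* **Bias unit.**  Bias is computed per bin; a nucleosome-level readout
  (`bias_at_dyads`) maps called dyads onto bias bins for users who prefer
  nucleosome resolution.  The default pipeline does not weight bias by
  nucleosome occupancy.

## 3. Internal callers

The BrdU-region and nucleosome callers are deliberately simple desk-scale
stand-ins for external peak/nucleosome callers, not reimplementations of
them; externally produced BED files can be imported instead.

* **Regions.**  Per bin, expected count = input count scaled by the
  library-size ratio, floored at the global mean BrdU count per bin
  (λ₀-floor); a bin is significant when count ≥ `min_fold`·λ and its upper
  Poisson tail survives Benjamini–Hochberg control at `alpha`.  Significant
  bins within `merge_gap` bins merge; regions shorter than `min_width` are
  dropped.  Defaults: `min_fold` 2, `alpha` 0.01, `merge_gap` 2 bins,
  `min_width` 500 bp.  Region calling should use coarser bins than the bias
  statistics: with a per-bin mean of μ expected counts against background λ,
  per-bin power is only ~75% at μ ≈ 15 but ≈ 98% at μ ≈ 30, so the reference
  scenario bins at 1 kb where bias profiles bin at 500 bp.  Raising
  `min_fold` or tightening `alpha` can only shrink the called set.
* **Nucleosomes.**  Pooled coverage at ≤ 20 bp bins, centered moving-average
  smoothing over `smooth_window` (60 bp), local maxima accepted greedily by
  descending height under a `min_separation` (120 bp) exclusion zone, ties
  broken toward the smaller coordinate (plateaus yield their leftmost bin).
  Dyad resolution is limited by the bin width (± bin/2) plus midpoint jitter.

## 4. Validation scenarios and problem sizes

All scenarios (in `espan.scenarios`) simulate with the package's generator
and analyze with the package's pipeline; every random stream derives from one
seed.

* **Null symmetry** — 50 origins, `p_lead` 0.5, `p_retain` 0.9, depth 2×10⁵,
  2 replicates: mean leading-bias score within 2 SE of zero; arm rank-sum p
  well above significance; fraction of metaprofile positions whose ±2 SE
  band covers zero.  On that last quantity: for two replicates the band of a
  mean-zero profile covers zero at P(|Cauchy| ≤ 2) = 70.5% of positions —
  the ratio of the sum to the difference of two iid normals is Cauchy — so
  observed coverages near 0.7 are the *correct* behavior of the ±2 SE rule
  at R = 2; ≥ 90% coverage would require about ten replicates.
* **Transfer-probability recovery** — `p_lead` ∈ {0.2, 0.35, 0.5, 0.65,
  0.8}, 50 origins, depth 5×10⁵, 2 replicates: the mean leading-bias score
  is strictly increasing and sign-matched to `p_lead` − 0.5 (the
  lagging-biased and leading-biased mutant archetypes).  Note the score is a
  mean of per-bin log ratios of small counts, which exaggerates magnitudes
  relative to the population log-odds; the monotone ordering and signs, not
  the absolute values, are the validated quantities.
* **Reduced-retention signature** — wild type `p_retain` 0.9 vs mutant
  0.585 (= 0.65×), both `p_lead` 0.5; 162 origins (matching the size of a
  fission-yeast early-origin set), depth 5×10⁶, 2 replicates.  Expected:
  per-strand density percent change ≈ −35% on *both* strands (Welch
  p ≪ 0.001) while the leading-bias score shift stays within its pooled SE —
  "less transfer to both strands, symmetry preserved".  The deep sequencing
  is needed because per-strand per-bin BrdU denominators are thin in the
  background-dominated regime; at low depth the ratio estimator grows heavy
  tails.  The 50-origin variant of this comparison has an irreducible
  ±2–3 percentage-point placement noise per strand, which is why the larger
  origin set is the reference condition.
* **Caller recovery** — 50 origins, depth 5×10⁵: Jaccard between called BrdU
  regions (1 kb bins) and true nascent intervals ≈ 0.98; nucleosome dyads on
  a 60 kb single-origin chromosome at ~60 reads/nucleosome recovered within
  ±20 bp for ≥ 95% of true dyads.

## 5. What the simulator does not model

Sequence-level features (no real bases/qualities, no alignment or mapping
error), Okazaki-fragment granularity (the lagging nascent strand is one
continuous strand — only strand identity matters to the bias), replication
timing heterogeneity and origin-firing stochasticity, sub-nucleosomal
repositioning (one shared dyad lattice per locus), di-nucleosome fragments,
co-occurring marks (parental XOR new), and H2A–H2B dynamics.  Passing the
validation scenarios therefore demonstrates correctness of the quantification
chain under the stated generative assumptions, not robustness to alignment
artifacts or timing structure in real libraries.

## 6. Reproducibility

All stages are deterministic given the config seed: states, sample
substreams (derived from seed × sample kind × replicate), and downstream
statistics.  The CLI writes a run log with a configuration hash, package
versions, and per-stage record counts; rerunning on the same inputs
regenerates byte-identical tables.
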