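# espan

Strand-resolved analysis of nascent-chromatin sequencing (eSPAN), with a
replication-fork chromatin simulator for end-to-end validation.

## The problem

During DNA replication, parental histones — carrying marks such as H3K4me3 —
are recycled behind the fork onto the two daughter duplexes, while newly
deposited histones (marked by H3K56ac) fill the remaining gaps.  eSPAN
(enrichment and sequencing of protein-associated nascent DNA) measures where
a chromatin mark sits on nascent DNA *per strand*: a mark ChIP is followed by
BrdU immunoprecipitation of denatured nascent single strands, so each
sequenced fragment reports the Watson or Crick strand of a daughter duplex.
Around a bidirectional origin, the nascent **leading** strand is the Watson
strand on the right arm and the Crick strand on the left arm (and vice versa
for the lagging strand), so strand-resolved counts translate directly into
leading/lagging occupancy.

This package implements the quantification used in such studies:

* strand assignment from SAM flags (first-in-pair forward → Watson);
* binned strand coverage and BrdU-IP ("MNase-BrdU-IP") normalization:

  `D(s, b) = (CPM_eSPAN(s, b) + c) / (CPM_BrdU(s, b) + c)`

* the per-bin **eSPAN bias** `log2(D(Watson, b) / D(Crick, b))`;
* origin-centered metaprofiles with the replicate confidence rule
  (mean ± 2·SE across biological replicates);
* per-origin arm summaries and the **leading-bias score**
  `(right-arm mean − left-arm mean) / 2` (positive = leading-strand
  enrichment), with Wilcoxon rank-sum arm tests (exact by enumeration for
  small samples);
* leading/lagging density summaries around origins and between-strain
  comparisons (percent change, Welch *t*-test) — the readout that
  distinguishes "less transfer to both strands" (a symmetric density drop)
  from "asymmetric transfer" (a bias shift);
* simple internal BrdU-region and nucleosome-dyad callers standing in for
  external peak/nucleosome callers at desk scale.

Because the real deposited datasets are not required, the package ships a
generative simulator (`espan.sim_fork`) of the full experiment — six samples
per strain (Input, MNase-BrdU-IP, two ChIPs, two eSPANs), parental retention
probability `p_retain`, leading-strand transfer probability `p_lead`, new
histone fill-in, ChIP off-target noise, and BrdU-IP leakage background — so
every pipeline stage is verifiable by parameter recovery.  See
`docs/methods.md` for the model and its assumptions.

## Worked example

```python
import espan

# a wild-type-like strain with leading-biased transfer (p_lead = 0.7)
cfg = espan.default_config(n_origins=12, p_retain=0.9, p_lead=0.7,
                           depth=500_000, seed=42)
lay = espan.build_layout(cfg)
state = espan.simulate_replication(lay, cfg)
print(espan.truth_summary(state).head(3).to_string(index=False))

espan_cov = espan.bin_coverage(
    espan.generate_reads(state, "espan_parental"), lay.genome_length, 500)
brdu_cov = espan.bin_coverage(
    espan.generate_reads(state, "mnase_brdu_ip"), lay.genome_length, 500)
bias = espan.compute_bias(espan.normalize_density(espan_cov, brdu_cov))
arm = espan.arm_bias_summary(bias, lay.origins, window_bp=5000)
print(f"mean leading-bias score: {arm['leading_bias_score'].mean():.3f}")
u, p = espan.wilcoxon_arm_test(arm["left_mean_bias"].to_numpy(),
                               arm["right_mean_bias"].to_numpy())
print(f"left vs right arm rank-sum: U={u:.0f}, two-sided p={p:.2e}")
```

prints

```
 origin_index  origin_pos  n_slots  n_retained  n_leading  n_lagging  leading_fraction
            0     1250000      121         113         76         37          0.672566
            1     3750000      121         109         68         41          0.623853
            2     6250000      121         104         72         32          0.692308
mean leading-bias score: 2.846
left vs right arm rank-sum: U=0, two-sided p=3.66e-05
```

Reading this: each origin has 121 nucleosome slots in its 20 kb nascent
window; ~90% of parental nucleosomes were retained, ~70% of those landed on
the leading daughter (`leading_fraction` recovers `p_lead = 0.7`).  The
pipeline, seeing only the simulated reads, reports a positive leading-bias
score at every origin (left arms Crick-shifted, right arms Watson-shifted),
and the rank-sum test on the twelve left-arm vs right-arm means is strongly
significant.  With `p_lead = 0.5` the score collapses to ~0 and the test
goes null.

The same pipeline runs from the shell:

```bash
espan simulate -c config.yaml -o out/          # 6 sample SAMs per replicate + truth
espan bias -c config.yaml -m out/manifest.yaml -o results/ --wt wt --mut mrc1-3A
espan compare results/wt/parental.density.tsv results/mrc1-3A/parental.density.tsv \
      -o comparison.tsv
```

`espan bias` writes, per strain and mark: bias bedGraphs per replicate, a
metaprofile TSV + figure with the ± 2 SE ribbon, an arm summary with the
rank-sum test, a bias heatmap, per-origin leading/lagging densities, and a
run log with the config hash and per-stage counts.

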