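# netmig

Connectome-based case–control analysis on a 379-region whole-brain
parcellation, built for small clinical cohorts (tens of subjects) such
as migraine case–control studies. The package answers three questions
about a patient group versus a healthy control group:

1. **Can functional connectivity classify the groups, and which
   couplings drive it?** Pearson correlations between the BOLD time
   series of all 379 regions (379² = 143,641 self-inclusive
   correlations; 71,631 unique region pairs as features) feed a
   gradient-boosted tree classifier (XGBoost) under stratified 5-fold
   cross-validation, scored by mean held-out AUC-ROC. Per-subject
   additive TreeSHAP attributions give each pair feature a magnitude
   (mean |attribution|) and a direction (sign of the value–attribution
   association), and region scores aggregate into per-network mean
   importances.
2. **Where is a patient's connectivity anomalous?** For every pair
   feature the control cohort supplies a median and a median absolute
   deviation (raw MAD); a patient's value is an anomaly when
   |x − median| / MAD ≥ 3. Anomalies are tallied per large-scale
   network, per patient and as group means.
3. **Which structural hubs shift?** Weighted PageRank centrality of
   the streamline-count adjacency matrix, converted to ranks 1–379,
   listed in control-median order; regions whose patient-vs-control
   median rank shifts by ≥ 20 positions are flagged with a direction.

Because cohorts like this are rarely shareable, `netmig` includes a
first-class synthetic cohort generator (latent network factors + planted
pair effects for the time series; log-normal streamline graphs with
persistent hubs + planted hub boosts for the structural side) that
reproduces the study design — 31 patients vs 17 controls, a 26/31 vs
8/17 female imbalance, ~300,000 streamlines per brain — and is what the
test suite uses for planted-effect recovery experiments. See
`docs/methods.md` for the models and all defaults.

## Worked example

Plant two effects in an otherwise null cohort — a weakened
Language–Salience coupling (left area 45 ↔ left area 23c) in patients'
functional data, and a 1.5× strengthened right-amygdala hub in their
structural data — then recover both:

```python
import netmig

atlas = netmig.build_default_atlas()
cfg = netmig.SynthConfig(
    fc_effects=[("L_45", "L_23c", -0.4)],
    hub_effects=[("R_Amygdala", 1.5)],
    seed=0,
)
cohort = netmig.generate_cohort(cfg, atlas)

cv = netmig.crossval_classify(cohort)
print(f"mean held-out AUC over 5 folds: {cv.mean_auc:.3f} +/- {cv.sd_auc:.3f}")

imp = netmig.directional_importance(cohort)
print(imp.top(3)[["region_a", "region_b", "magnitude", "direction"]].to_string(index=False))

net = netmig.aggregate_by_network(imp, atlas)
print(net.table.head(3).to_string(index=False))

ranks_p = netmig.cohort_rank_vectors(cohort.patients)
ranks_c = netmig.cohort_rank_vectors(cohort.controls)
dev = netmig.rank_deviation(ranks_p, ranks_c, atlas.names)
print(dev.flags.to_string(index=False))
```

which prints:

```text
mean held-out AUC over 5 folds: 0.936 +/- 0.094
region_a    region_b  magnitude  direction
   L_23c        L_45   1.979431         -1
  L_SCEF        L_45   0.305127         -1
   R_47s L_Accumbens   0.269315         -1
 network  mean_importance
Language         0.172646
Salience         0.088500
  Limbic         0.017335
    region  control_median_rank  patient_median_rank direction
      R_V6                161.0                138.0    higher
    R_FOP4                193.0                221.0     lower
R_Amygdala                218.0                 80.0    higher
    L_PFcm                268.0                248.0    higher
```

The classifier separates the groups well above chance; the planted
pair is the top feature by an order of magnitude, with the negative
direction of a coupling that is *low* in patients; its endpoint
networks (Language, Salience) top the network table; and the boosted
right amygdala is flagged with "higher" centrality (median rank 218 in
controls vs 80 in patients), among a few borderline rank wobbles.

## Command line

Each stage is also a subcommand operating on plain CSV/TSV files:

```bash
netmig synth --config synth.yaml --seed 0 --out cohort/
netmig fc --cohort cohort/ --out fc/
netmig classify --cohort cohort/ --grid grid.yaml --seed 0 --out results/
netmig mad --cohort cohort/ --out results/
netmig pagerank --cohort cohort/ --out results/
netmig demographics --cohort cohort/ --out results/
netmig all --config run.yaml --seed 0 --out results/
```

`netmig all` runs every stage and writes a `manifest.json` with the
seed, package versions and SHA-256 checksums of every output; two runs
with the same config and seed are byte-identical.

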