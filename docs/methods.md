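# Methods

## The model and its assumptions

`connfp` treats a subject's structural connectome as a set of *m*
compositional profiles, one per region: row *i* of the fingerprint matrix
is the probability vector of relative connectivity from region *i* to all
targets. The statistical question is whether these profiles are
group-structured, and it is answered nonparametrically: the only
assumption of the node-level test is exchangeability of subjects across
groups under the null. No distributional form is imposed on connection
probabilities — appropriate, since tractography-derived probabilities are
bounded, skewed and zero-inflated.

### Fingerprint computation

Each voxel's counts are normalized to the voxel's total *before*
averaging over the seed's voxels. This weights every voxel equally; the
alternative (pooling counts across voxels, then normalizing once) weights
voxels by how many of their samples reached any target, and the two
coincide exactly only when all voxel totals in a seed are equal — the test
suite demonstrates the inequality by brute force on small instances.
Voxels from which no sample reached any target have an undefined
per-voxel ratio; they are excluded from the average with a logged
warning, and the divisor is the number of contributing voxels, which
preserves the sum-to-1 property of the fingerprint. Self-connections are
not tracked: the seed's own column is required to be zero, and each
fingerprint lives on the other *m* − 1 targets.

A region × region count matrix (no voxel detail) is accepted as a
degraded fallback via `fingerprint_from_region_counts`, documented as a
deviation from the voxel-wise definition.

### Similarity and the regularization factor α

Similarity is `exp(-d/α)` of the L1 fingerprint distance. α is half the
maximum distance over **all** nodes and subject pairs, pooled across
groups (the literal global reading, adopted over a conceivable per-node
variant). It is computed once before testing and reused inside
permutations — this is exact, not an approximation, because relabeling
group membership does not change the pooled set of pairwise distances. α
is recorded in the run manifest. Only the exponential-L1 measure ships;
the similarity stack is the plug-in point for alternatives.

### Node-level permutation test

The statistic is the mean within-group minus mean between-group pairwise
similarity, over unordered pairs with the diagonal excluded. The diagonal
(s = 1, constant) is excluded because with unequal group sizes it would
enter within- and between-group averages asymmetrically and bias the
permutation null. With more than two groups, within-group pairs pool
across all groups, so the test runs unchanged for multi-group designs.

The p-value uses the add-one estimator: with *N* − 1 random relabelings,
p = (1 + #{T_perm ≥ T_obs}) / N, so p ≥ 1/N and the test is valid (never
anti-conservative) under exchangeability. Permuted values exactly equal to
the observed one count against rejection (ties handled with ≥, at a 1e-12
tolerance). Whenever the number of distinct size-preserving relabelings is
at most N, the test switches to exhaustive enumeration and the p-value is
exact. The same relabelings are shared across nodes, which couples the
node-level p-values through one null sample but leaves each marginal
p-value exact and makes the m-node test a single matrix product.

Across nodes, Benjamini–Hochberg step-up FDR at q = 0.05 is the default
(`method="by"` switches to Benjamini–Yekutieli for arbitrary dependence);
BH is the field's default choice and is what the rejection flags use.

### Post hoc pseudo-t tests

Within a flagged node, each of its m − 1 relative connection
probabilities is compared between the two groups. The pseudo-t
standardizes the observed mean difference (group 1 minus group 2) by the
mean and SD of its permutation distribution; with balanced designs the
permutation mean is ≈ 0, but centering is kept for unbalanced ones. The
test is two-sided, because both reduced and increased relative
connectivity are of interest, and the sign convention is: negative
pseudo-t = larger in the second group (the patient group in a
case-control design). FDR correction uses only the node's own m − 1
p-values: fingerprints of different nodes are normalized independently,
so correction per node is legitimate and more powerful. A degenerate
permutation distribution (all pooled values identical, SD = 0) yields
pseudo-t = 0, p = 1 with a warning; this occurs routinely for target
pairs with no samples in any subject.

`two_sample_permutation` exposes the same machinery as a generic
two-sample test (e.g. demographic comparisons).

### Clinical correlations

Pearson r with two-sided t-based p (n − 2 df) between flagged connection
probabilities and clinical score columns, computed by default in the
second group only (symptom scores are typically defined for patients),
with pairwise deletion of missing values and a minimum of 3 complete
pairs. The output is flagged as not multiplicity-corrected; it is an
exploratory companion, not a confirmatory test.

## The synthetic-cohort generator

The generator is a Dirichlet–multinomial hierarchy — the minimal
generative model matching the data type (compositional profiles plus
count sampling); it is a stand-in for real cohorts, with every parameter
exposed:

| parameter | default | meaning |
|---|---|---|
| `m` | 20 | regions (nodes) |
| `voxels_per_region` | 20 | seed voxels per region |
| `samples_per_voxel` | 5000 | tract samples propagated per voxel (the standard probtrackx setting) |
| `n_per_group` | (16, 17) | subjects per group (reference case-control sizes) |
| `baseline_concentration` | 0.5 | Dirichlet concentration of the population profile; scalar < 1 gives sparse, hub-dominated profiles as seen in real tractography; a per-target vector shapes the expected profile |
| `subject_dispersion` | 150 | concentration of the subject-level Dirichlet around the population profile; larger = more homogeneous subjects |
| `effects` | () | (seed, target, factor, group): multiplies the target's concentration before the subject draw, planting hyper- (factor > 1) or hypo- (factor < 1) connectivity in *relative* probability |
| `distance_attenuation` | off | optional positive (m, m) reweighting of the population profiles shared by all groups, emulating the distance bias of probabilistic tractography |

Per node a population profile is drawn from Dirichlet(baseline) over the
m − 1 targets; per subject, a profile from Dirichlet(dispersion ×
population profile), with effect multipliers applied to affected-group
subjects before the draw; per voxel, counts from
Multinomial(samples_per_voxel, subject profile). Everything is
deterministic under the spec's seed, and `write_fixture` round-trips a
cohort through the exact on-disk layout the readers consume.

**What the simulator does and does not emulate.** It reproduces the data
type (integer counts, compositional structure, between-subject
variability, asymmetric fingerprints) and plantable group effects. It
does **not** emulate spatial voxel correlation within a region (all
voxels of a subject share one profile), distance-dependent false-positive
streamlines beyond the optional shared attenuation, head-motion or
registration artifacts, or realistic atlas topology. Passing the
validation suite therefore demonstrates the *statistical* correctness and
calibration of the machinery on data of the right type — not robustness
to tractography's systematic biases, which must be judged on real data.

## Validation scenarios and problem sizes

The calibration and recovery runs use m = 20 regions, 20 voxels/region
and N = 2000 permutations per test: null calibration over 500 zero-effect
cohorts of 8+8 subjects (per-node rejection rate at 0.05 and empirical
BH FDR), and recovery over 100 cohorts of 16+17 subjects with two planted
factor-3 hyper-connectivity effects. In the recovery scenario the two
planted targets are given baseline concentration 3.0 (vs 0.5 elsewhere,
expected baseline probability ≈ 0.2), so the effect lands on a prominent
connection: a factor-3 concentration change on an essentially absent
connection perturbs the fingerprint negligibly and is not a meaningful
"strong effect". Exhaustive-vs-Monte-Carlo agreement is checked at 5+5
subjects (252 relabelings).

## Numerical choices

- Normalization assertions use a 1e-12 absolute tolerance.
- Permutation tie comparisons use ≥ with a 1e-12 tolerance, counting ties
  against rejection.
- Pseudo-t uses the sample SD (ddof = 1) of the permutation distribution;
  at N ≥ 2000 the distinction from the population SD is negligible.
- Node order is the atlas file order everywhere; mismatched orders raise,
  nothing is silently re-sorted.
- All randomness flows from one master seed, split per pipeline stage via
  `numpy.random.SeedSequence`; tables are written with round-trippable
  float formatting, so identical seeds give byte-identical outputs.
- Radial diagrams default to linear radial distance with ring labels at
  {0.05, …, 0.3}; a log-radius variant is available. Group CIs are
  mean ± t × SE per target (bootstrap CIs are a possible extension).

## Known limitations

- The exponential-L1 similarity is the only measure shipped.
- The post hoc tests are two-group only (the node test is multi-group).
- No correction for tractography's distance bias is attempted; the
  simulator's attenuation option only probes its shared-confound form.
- Region-level count input loses the voxel-equal weighting of the
  fingerprint definition.
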