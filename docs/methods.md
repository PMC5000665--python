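# Methods

## The quantity being estimated

A tag SNP *t* is assumed to proxy an unknown functional variant *f*
nearby. In a reference population R, the candidate set for a distance
window *W* (kb) is

    C_W = { v : |pos(v) − pos(t)| ≤ 1000·W, v ≠ t, r²_R(t, v) defined and ≥ θ }

with θ = 0.80 by default. If *f* is drawn uniformly from C_W, the
probability that *t* still tags it in a target population P is

    π_P(W) = (1 / |C_W|) · Σ_{v ∈ C_W} 1[ r²_P(t, v) defined and ≥ θ ]

`evaluate_exact` computes π directly; `evaluate_monte_carlo` estimates it
by n_sims uniform draws with replacement (the original study's procedure;
10⁶ draws by default). The two have the same estimand, so exact mode is
the default and Monte Carlo is retained for fidelity and for checking the
binomial error bound |π̂ − π| ≤ 5·sqrt(π(1−π)/n_sims). Since π is a
rational number k/|C_W|, with e.g. four candidates the only achievable
exact values are 0, 0.25, 0.5, 0.75 and 1 — percentages reported for
small candidate sets should be read as rounded fractions.

Conventions fixed here and recorded in output metadata:

* **Windows are symmetric and cumulative**: |pos − tag_pos| ≤ 1000·W, so
  C_5 ⊆ C_10 ⊆ C_50 ⊆ C_100. Candidate counts are therefore
  non-decreasing in W.
* **The tag itself is excluded** from C_W; including it would inflate
  every proportion.
* **Undefined r² counts as not tagged.** r² is undefined when either
  locus is monomorphic among pairwise-complete observations or fewer
  than two remain. A population where the tag is monomorphic gets
  π = 0 with `tag_monomorphic = True` — the tag carries no information
  there, which is distinct from "no candidates exist" (reported as
  n_candidates = 0 with proportion NA).
* A tag monomorphic in the *reference* population makes candidate
  enumeration undefined and is an error.

## r² estimators

* **genotype mode** (default): squared Pearson correlation of per-sample
  allele dosages (0/1/2). This is PLINK's default r² and works on
  unphased data.
* **haplotype mode**: r² = D²/(p_A q_A p_B q_B) on phased haplotype
  frequencies, D = p_AB − p_A p_B.

Both use pairwise-complete observations and record n_used. Under random
mating (haplotypes paired independently) the two agree closely; the test
suite checks agreement within 0.02 on a 2000-sample panel. Both are
invariant to swapping ref/alt labels and symmetric in their arguments;
floating-point results are clipped into [0, 1] at the top boundary only.

## Seeding

All Monte-Carlo draws use numpy's PCG64 via `default_rng`. In a full
study the per-(tag, window, population) seed is
`crc32("tag|window|pop") XOR base_seed`, masked to 31 bits, so adding or
removing a population never perturbs another population's draws, and
identical inputs give byte-identical results TSVs.

## Synthetic panels

The generator emulates the statistical structure the pipeline assumes in
real data — shared ancestry with population-specific LD decay and drift —
without being a population-genetics-grade simulator.

* **Founders**: n_founders haplotypes with independent per-site alt
  frequencies drawn Uniform(0.10, 0.90). No mutation model, recombination
  map, selection or explicit demography.
* **Mosaics**: each population's haplotypes are mosaics over its founder
  pool, switching source founder between adjacent sites with probability
  `switch_prob`; `extra_switch_rounds` re-mosaics the pool, accelerating
  LD decay. `drift_bottleneck` resamples that many founders with
  replacement as the population's pool, producing drift and possible
  monomorphism (bottleneck 0 is rejected as infeasible).
* **Planted proxies** copy the tag column exactly (r² = 1) in populations
  where tagging is preserved; elsewhere the column is re-randomized as
  Bernoulli draws at the tag's panel-wide frequency, destroying the
  correlation while keeping the site polymorphic in expectation.
* **Forced monomorphism**: `monomorphic_tag_pops` sets the tag column to
  the reference allele in the listed populations, guaranteeing
  monomorphic-tag cases at every seed (drift alone cannot guarantee
  them).
* **Truth is measured, not assumed**: after the matrix is built, the
  TruthTable (candidates per window, per-population tagged counts,
  monomorphic flags) is computed from the finished panel with the same
  r² definitions the pipeline uses. Tests therefore compare the
  pipeline's orchestration against direct measurement, with no
  model-approximation error. A planted proxy can occasionally fail to
  clear θ in a small preserving population, or a background variant can
  incidentally clear it; the measured truth absorbs both.

All randomness flows from the scenario seed through named substreams
(founders / per-population mosaics / proxy re-randomization); the same
seed yields bit-identical panels.

`paperlike_scenario` fixes a 26-population, 5-region design (12 samples
per population, 121 variants at 2 kb spacing over 240 kb, tag central):
a European reference (CEU) preserving all 16 planted proxies, regional
preservation probabilities grading from 0.92 (Europe) down to 0.20
(Africa), extra switch rounds outside Europe, bottlenecks in two American
populations, and two African populations with a monomorphic tag. The
sizes keep a full exact + Monte-Carlo (10⁵ draws) study under a few
seconds while leaving every window with a non-trivial candidate set.
Passing tests on these panels demonstrate the pipeline's correctness
given a panel; they do not validate the generator as a model of human
demography, and real-panel candidate sets are larger and include
imperfect (0.8 ≤ r² < 1) proxies.

## Numerical and degenerate-input choices

* Missing genotype calls are allowed (encoded −1) and handled
  pairwise-complete; 1000 Genomes Phase 3 has none, so results there are
  unaffected.
* Only biallelic SNVs are retained at load; multi-allelic sites and
  indels are dropped and counted in the load report. No MAF filter
  beyond polymorphism is applied.
* Unphased or half-called genotypes: loading succeeds with
  `phased = False`; haplotype-mode r² then raises a precise error
  directing to genotype mode (fail late, at the point of use).
* Coordinates are 1-based inclusive throughout, matching VCF; region
  strings are `contig:start-end`.
* Proportions are written with 4 decimals; NA marks "no candidates".

## Known limitations

* One tag, one contig per study; no imputation, kinship inference,
  D′/haplotype-block statistics, or EM haplotype-frequency estimation
  for unphased data; no polygenic risk modelling.
* Relatedness exclusions are taken as an explicit input list; the
  package does not decide kinship.
* The published-number reproduction requires the 1000 Genomes Phase 3
  release-20130502 slices staged locally (`data/1kg/`); they are too
  large to redistribute with the package.
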