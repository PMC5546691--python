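# Methods

## The BC% decomposition

Bray-Curtis similarity between two OTU vectors is `BC = 2·C/(S_i + S_j)`,
with `C` the summed lesser abundances over shared OTUs and `S_i`, `S_j`
the sample sizes. Three input conventions are exposed, because published
descriptions of "Bray-Curtis on OTU tables" are often ambiguous between
them:

* **abundance** (default): both vectors are converted to per-sample
  relative abundance first, so `S_i = S_j = 1` and `BC = Σ min(p, q)`.
  This is the standard quantitative Bray-Curtis, invariant to sequencing
  depth, and the variant used throughout the model unless overridden.
* **counts**: the raw-count form, depth-sensitive; provided for
  completeness.
* **presence**: binarized inputs, where BC reduces exactly to the Dice
  coefficient `2|X∩Y|/(|X|+|Y|)` — the "number of shared species"
  reading of the formula.

For a focal sample `X_n`, the neighbor set contains its own previous
sample (inner slot) and, for each compartment adjacent to X in the
declared adjacency model, that compartment's current and previous samples
(2k+1 slots for k adjacent compartments; five in the canonical
three-compartment, fully connected case). "Previous" always means the
previous *sampled* time index of that compartment, so irregular sampling
grids (day 2, 7, 11, …) need no special handling. The BC values of the
neighbor set are normalized to percentages summing to 100; the inner
slot's share is the compartment's stability, and the per-source sums of
the spatial slots are the external influences. Aggregating over a time
window gives the interaction network (mean inner% per node, mean external%
per directed edge; the per-edge mean of the two slot terms' average is
also reported for the "average of current and previous" convention).

### Degenerate and boundary cases

* **Zero similarity budget** (the focal sample shares nothing with any
  neighbor): the decomposition is reported as *undefined* and excluded
  from aggregates, rather than assigned a uniform split — a uniform split
  would fabricate influence where the data show none.
* **Boundary time points**: the first sample of a compartment has no
  inner slot; its decomposition is computed over the slots that exist
  (the 100% budget semantics are preserved) and flagged `boundary` so
  users can exclude such points. The inner share of a boundary point
  without an own-past sample is 0 by construction.
* **Missing samples** (a compartment skipped a time point): under the
  default `nearest-earlier` policy the spatial-current slot is filled by
  that compartment's latest earlier sample, with the time lag recorded in
  the slot, and the spatial-previous slot slides back behind the
  substitute; under `drop-slot` the slot is omitted and the budget
  renormalizes over the remaining neighbors. `nearest-earlier` is the
  default because field sampling grids are commonly uneven and the full
  five-slot stack keeps time points comparable.
* **Replicates**: neighbor lookup is only well defined with one sample
  per (compartment, time); tables carrying replicate labels are rejected
  by the time-series model and should be pooled or subset first.
* The default aggregation windows are the first and the last decomposable
  time point — the natural "early versus late system state" contrast; any
  inclusive time ranges can be supplied instead.

## Supporting metrics

* **Shannon-Wiener** `H = −Σ p log p` (natural log by default, base
  selectable), with observed richness.
* **Jaccard** `|X∩Y|/|X∪Y|` on presence/absence.
* **Rarefaction**: expected richness at depth d is the hypergeometric
  closed form `Σ_i [1 − C(N−N_i, d)/C(N, d)]`, evaluated with log-gamma;
  tests confirm agreement with seeded Monte-Carlo subsampling within
  Monte-Carlo error.
* **UPGMA** delegates to SciPy's average-linkage implementation and
  converts the linkage to an ultrametric tree (each merge at half its
  merge distance). Ties are broken by SciPy's deterministic ordering.
* **Weighted UniFrac** is computed by a single post-order branch walk:
  raw form `Σ_b l_b·|p_b − q_b|` over branches, normalized form divided
  by `Σ_b l_b·(p_b + q_b)`; inputs are converted to relative abundance.
  The walk is implemented in-package because available library routines
  coerce abundances to integer counts, which breaks the float
  relative-abundance contract; tests cross-check against scikit-bio on
  integer inputs to machine precision. On a star tree with unit branch
  lengths the raw form equals `2·(1 − BC)` exactly, which pins the
  BC↔UniFrac correlation to r² = 1 there and anchors the cross-metric
  validation; on arbitrary random trees the correlation remains strongly
  negative (similarity vs distance) but not exactly linear.
* **Three-set sharing**: pairwise intersection counts are interpreted as
  *inclusive* of the triple overlap, and exclusive Venn regions are
  derived by inclusion-exclusion, erroring on impossible (negative)
  regions. Percentages are reported per set relative to that set's own
  total, at one-decimal rounding by default (full precision available).
  On the published worked-example counts (totals 12,096/11,987/5,338;
  pairwise 4,108/1,096/1,171; triple 783) this reproduces the printed
  percentages, except that the consumer-unique share derives to 62.8%
  where 62.7% was printed — inclusion-exclusion on the printed counts
  admits only 7,600/12,096 = 62.83%, so the derived value is reported.
  (The same counts imply a union of 23,829 OTUs versus a printed grand
  total of 23,802; the discrepancy is inherited from the source counts.)

## Read and OTU filters

Read QC keeps a read iff length > 200, mean Phred quality > 25 (strict
inequalities) and, by default, no base outside A/C/G/T; the checks are
applied in that order and each dropped read is counted under the first
failure. Quality encoding defaults to Phred+33 (Phred+64 selectable).
The rare-OTU filter drops OTUs with fewer than 3 reads *pooled across all
samples* (i.e. singletons and doubletons), the usual denoising rule for
pooled OTU tables; the threshold is a parameter. "Normalization" defaults
to per-sample relative abundance (deterministic); seeded rarefaction to a
common depth is provided as an alternative for depth-sensitive analyses.

## The simulator

`simulate_system` evolves one latent relative-abundance profile per
compartment:

```
pi_c(t+1) = (1 − Σ m_t(c'→c)) · perturb(pi_c(t)) + Σ m_t(c'→c) · pi_c'(t)
```

with `perturb` a Dirichlet resample centered on the current profile
(parameter = concentration × profile, restricted to the current support —
profiles stay exactly on the simplex, and OTUs can drift to extinction but
never spontaneously reappear). Migration mixes *latent* profiles, i.e.
exchange happens in the system before sequencing; observed counts are a
multinomial draw per sample at the configured depth, modelling finite
sequencing effort. All randomness flows from one seed.

Default scale — 300 OTUs, 3 compartments, 11 time points, 8,000 reads per
sample — mirrors a small pyrosequencing survey (tens of samples at a few
thousand reads each) while staying desk-cheap; the constant-exchange
default migration is 0.05 per ordered pair, and the default drift
concentration 200 gives mild step-to-step turnover. `init_overlap` sets
the fraction of the OTU pool shared between compartments at t = 0 (0.2 by
default; 1.0 additionally starts all compartments from one common
community).

`stabilizing_scenario` encodes a system that settles: migration decays
geometrically (factor 0.65 per step, from initially strong
substrate↔consumer exchange: S→A 0.35, A→S 0.30, the water edges ≤ 0.10)
while drift concentration grows mildly (50 × 1.2^t). The mechanism matters:
early on, heavy immigration both perturbs each community and keeps the
compartments alike, so the inner share is small; once exchange dies out,
*persistent* independent drift makes the compartments diverge from each
other while each still tracks its own past closely — inner BC% rises,
external BC% falls. (If drift also vanished, between-compartment
similarity would freeze at its early high level and the inner share would
plateau instead.)

### What the simulator does and does not emulate

It captures compositional exchange, neutral drift, uneven pool overlap
and multinomial sequencing noise. It does not model selection or
environmental filtering, OTU-level phylogenetic structure in the
dynamics (trees for UniFrac tests are generated independently of the
abundance process), PCR/primer bias, chimeras, or depth variation between
samples. Tests passing on simulated data therefore demonstrate the
correctness and sensitivity of the *method* under known exchange
dynamics, not the biological accuracy of any particular field system.

## Numerical choices

* Budget percentages carry full double precision; conservation
  (inner + Σ external = 100) holds to ~1e-13 and is asserted at 1e-6.
* Rarefaction uses log-gamma differences, stable for counts ≫ 10⁴.
* Abundance-mode BC of an all-zero vector, Shannon of an all-zero vector,
  Jaccard/Dice of two empty sets, and UniFrac of an empty sample are
  errors, not zeros.
* UPGMA requires a symmetric, zero-diagonal, non-negative matrix and is
  deterministic for a given input ordering.
* Weighted UniFrac is invariant to root placement in both forms (branch
  mass flips `p → 1−p` across the root leave `|p−q|` and `p+q`
  unchanged); the normalized form of two identical samples is defined as
  0 even though its ratio is 0/positive only for nonempty trees.

## Known limitations

* BC% is a relative budget: percentages of different focal samples share
  a scale (100) but not a similarity magnitude — a 50% inner share can
  mean strong self-similarity among strong neighbors or weak
  self-similarity among negligible ones. Inspect the raw `bc` column of
  the trajectory when absolute similarity matters.
* The decomposition is correlational; directed edges in the interaction
  network express shares of similarity, not measured transfer rates.
* With heavily unbalanced sampling grids the nearest-earlier policy can
  reuse one old sample in several slots; the recorded lags should be
  checked before interpreting such points.
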