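# bcflux

Quantifying how the microbial community of each compartment of an
ecosystem is shaped over time — by its own past versus by the compartments
it exchanges microbes with.

## The problem

In a multi-compartment system (for example an aquaculture pond with a
consumer *A*, an algal substrate *S* and the surrounding water *W*), the
16S OTU profile of every compartment changes through time, partly by
internal turnover and partly through microbial exchange with its
neighbors. `bcflux` implements a similarity-budget decomposition of this
process, built on the Bray-Curtis (BC) similarity

```
BC_ij = 2 C_ij / (S_i + S_j)
```

where `C_ij` is the sum over OTUs of the lesser of the two abundances and
`S_i`, `S_j` are the sample sizes (with relative abundances, `S_i = S_j =
1`). BC is 1 for identical composition, 0 for no shared OTUs, and varies
linearly in between — so BC values can be summed and expressed as
percentages.

For a focal sample `X_n` (compartment X at time n), BC is computed against
its five spatio-temporally adjacent samples: `X_{n-1}` (own past), and the
current and previous samples of each adjacent compartment (`Y_n`,
`Y_{n-1}`, ...). Normalizing these similarities to sum to 100% gives the
**BC% decomposition**:

* **inner BC%** — the share contributed by `X_{n-1}`: community
  stability, how much the compartment tracks its own past;
* **external BC%** per neighbor Y — the share of `Y_n` plus `Y_{n-1}`:
  the apparent influence of compartment Y on X.

By construction `inner% + Σ external% = 100` for every defined
decomposition, and the percentages are invariant to rescaling all BC
values. Averaging over a time window yields an interaction network whose
node weights are inner BC% and whose directed edge weights are external
BC%. Note that BC% measures a similarity budget, not directed transfer.

The package also ships the supporting machinery this kind of study needs:
FASTQ read QC and rare-OTU filtering, relative abundance and rarefying,
Shannon-Wiener diversity, Dice/Jaccard coefficients, analytic rarefaction
curves, UPGMA clustering, weighted UniFrac (for cross-validating BC
against a phylogeny-aware metric), three-compartment OTU-sharing (Venn)
percentages, and a seeded multi-compartment community simulator with
known migration/drift ground truth.

## Worked example

Simulate a stabilizing three-compartment system (migration decaying
geometrically, drift concentration growing) and run the BC% model:

```python
from bcflux import BCPercentModel, simulate_system, stabilizing_scenario

truth = simulate_system(stabilizing_scenario(seed=7))
res = BCPercentModel(truth.table).fit()
print(res.summary())
```

```
BC% spatio-temporal decomposition
  samples: 33, OTUs: 300, mode: abundance, policy: nearest-earlier
  decompositions: 33 (0 undefined, 3 boundary)

Inner BC% by compartment and time:
time_index    0     1     2     3     4     5     6     7     8     9     10
compartment
A            0.0  26.5  28.0  31.2  32.9  35.2  37.2  39.0  39.9  40.8  43.5
S            0.0  23.5  27.3  32.4  36.8  41.4  41.3  37.1  40.1  41.8  42.6
W            0.0  31.4  36.5  42.5  45.8  52.8  52.7  57.7  56.1  58.4  62.1

Mean external BC% (source -> target):
  A -> S:   44.8%
  A -> W:   28.6%
  S -> A:   44.5%
  S -> W:   26.3%
  W -> A:   23.3%
  W -> S:   22.1%
```

Each compartment's inner BC% rises over time (e.g. A: 26.5% → 43.5%) as
exchange decays — the communities stabilize — while water, the least
invaded compartment, is the most stable throughout. Time 0 has no
"own past" sample, so its inner share is 0 and the decomposition is
flagged as a boundary point. `res.trajectory` holds the long-format
per-term percentages, `res.interaction_network()` the windowed network
aggregates, and `res.plot_stacked()` the stacked-area view.

The same analysis is available from the shell:

```bash
bcflux simulate --scenario stabilizing --seed 7 --out sim
bcflux bcpct --table sim.table.tsv --meta sim.meta.tsv --out run
bcflux venn --table sim.table.tsv --meta sim.meta.tsv
```

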