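# asmpipe

**Quantifying niche-based vs. neutral community assembly from trait and
abundance survey data.**

`asmpipe` implements a stepwise community assembly analysis for local
communities sampled from a shared regional species pool — the motivating
system is littoral cichlid fish communities surveyed along 20 m × 4 m
transects, with per-species abundance counts, six continuous functional
traits per species, and three habitat variables per transect (depth,
sand cover, topographic complexity), transects grouped in sampling
clusters of three.

The central question: how much of local community composition is due to
**neutral (stochastic) sampling** from the pool, and how much to the two
classical niche processes, **habitat filtering** and **limiting
similarity** — and do the niche processes, even when rare, dominate the
observable trait–environment patterns?

## The model

A local community of richness *S* is modelled as the outcome of
removing species one at a time from the pool (size *S*\_pool) until *S*
remain. Each of the *S*\_pool − *S* removal steps applies one of three
operators:

* **stochastic** — remove species *i* with probability ∝ 1/*f*<sub>i</sub>,
  where *f*<sub>i</sub> is the number of transects where the species
  occurs (widespread species rarely drop out);
* **filtering** — remove the species farthest (Euclidean distance in
  standardized trait space) from the habitat optimum, taken to be the
  observed community's trait mean;
* **limiting similarity** — find the most similar pair of remaining
  species and remove the member whose second-nearest neighbour is
  closer.

The parameter is the step composition (*n*<sub>stoch</sub>,
*n*<sub>filt</sub>, *n*<sub>lim</sub>), reported as percentages of all
steps. It is inferred per transect by **ABC-SMC**: simulated communities
are summarized by four statistics — functional richness (FRic, convex
hull volume in a reduced trait space), functional evenness (FEve,
minimum-spanning-tree regularity), functional divergence (FDiv) and the
community trait means (CTM) — and accepted when their scaled distance to
the observed statistics falls below a shrinking tolerance. The run stops
at a final acceptance rate of 1 in 20,000; estimates average three
replicate runs.

Two downstream contrasts separate step counts from pattern strength:

* **trait–environment**: linear mixed models of each CTM on depth, sand
  and complexity (cluster random intercept, scaled variables, backward
  elimination, Nakagawa–Schielzeth conditional R²), applied to the
  observed data and — with the observed model formula — to ensembles of
  artificial communities simulated either from the best-fit posterior or
  fully stochastically;
* **composition–environment**: Bray–Curtis dissimilarity between
  transects against normalized environmental distance (Mantel
  permutation test, distance-decay slope), contrasted with the same
  relationship for fully stochastic artificial communities.

A synthetic-data generator produces full surveys with known process
mixes and an environment-linked trait optimum, so every stage is
testable end to end without field data.

## Worked example

```python
import numpy as np
from asmpipe import SynthConfig, generate_dataset, AbcConfig, fit_all

cfg = SynthConfig(n_species_pool=30, n_transects=12, n_clusters=4,
                  richness_range=(12, 18), true_mix=(70.0, 10.0, 20.0),
                  seed=11)
dataset, truth = generate_dataset(cfg)
table, fits = fit_all(dataset, AbcConfig(n_particles=200,
                                         stop_acceptance_rate=1/2000,
                                         n_replicates=3, seed=5))
print(table[["pct_stochastic", "pct_filtering", "pct_limiting"]].mean().round(1))
```

prints (seed 11, fitted at the reduced settings shown):

```
pct_stochastic    65.0
pct_filtering     20.2
pct_limiting      14.8
```

i.e. for a survey generated with a 70/10/20 stochastic/filtering/
limiting step mix (76/9/15 after restricting to the realized pool),
the survey-mean fit attributes about two-thirds of the removal steps to
stochastic sampling, with the niche share split between filtering and
limiting similarity. Per-transect estimates scatter considerably at a
single transect's information content, which is why the pipeline
reports replicate-averaged and survey-averaged values.

The same workflow is available from the shell:

```bash
asmpipe simulate --config cfg.yaml --out data/
asmpipe fit --abundance data/abundance.csv --traits data/traits.csv \
            --environment data/environment.csv --out fits.csv
asmpipe dissim --abundance data/abundance.csv --traits data/traits.csv \
               --environment data/environment.csv --perms 100000 --out dissim.json
asmpipe run --config cfg.yaml --out results/   # full pipeline + manifest
```

## Layout

| module | contents |
| --- | --- |
| `data_io` | domain types (trait table, transects, species pool), CSV readers/writers, validation, trait standardization and correlation pruning |
| `synthetic_data` | survey generator with known ground truth |
| `fd_metrics` | FRic / FEve / FDiv / CTM and the pooled summary engine |
| `stepcam_forward` | the three removal operators and the assembler |
| `abc_smc` | prior, move kernel, distance, ABC-SMC fitter |
| `null_ensembles` | fully stochastic and best-fit community ensembles |
| `trait_env_stats` | mixed models, backward elimination, conditional R², observed-vs-ensemble tables |
| `community_dissimilarity` | Bray–Curtis, environmental distance, Mantel, slope contrasts |
| `pipeline`, `cli` | orchestration with provenance manifest; `asmpipe` command |

See `docs/methods.md` for the modelling assumptions, parameter
defaults, and known limitations.
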