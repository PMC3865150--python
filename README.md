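# refrank

Choosing a reference ("housekeeping") gene is the first decision in any
RT-qPCR study: every target gene's expression is reported relative to it, so
an unstable reference silently distorts every downstream fold change.  The
standard stability programs — geNorm, NormFinder, BestKeeper, qBase-style
expression CV — routinely disagree about which candidate is most stable,
because they measure different things.  `refrank` runs all four algorithms on
a table of raw Ct values and merges their discordant rankings into a single
consensus ordering by Spearman-footrule rank aggregation, the approach used
to pick reference genes across tissues in livestock expression studies.

## What it computes

**Stability scores** (lower = more stable), from replicate-collapsed Ct
values and efficiency-corrected relative quantities
`q = (1 + E)^(Ct_min − Ct)` with `E = 10^(−1/slope) − 1` from the
standard-curve slope:

* **geNorm** — `M_j = mean_{k≠j} SD_samples( log2 q_j/q_k )`, with stepwise
  exclusion of the worst gene and the pairwise-variation curve `V(n, n+1) =
  SD( log2 NF_n/NF_{n+1} )` for choosing how many references suffice
  (`NF_n` = geometric mean of the top *n* genes).
* **NormFinder** — model-based decomposition of log expression into
  intra-group variance and shrunken inter-group bias; the stability value
  combines both.
* **BestKeeper** — per-gene SD and CV of raw Ct, plus Pearson correlation to
  the geometric-mean BestKeeper index.
* **Expression CV** — CV of quantities normalized by the all-gene
  geometric-mean factor.

**Consensus**: given m rankings of k genes, find the ordering c minimizing
`Σ_l w_l Σ_g |pos_c(g) − pos_l(g)|` (the weighted Spearman footrule).  Three
solvers: exhaustive enumeration of all k! orderings (k ≤ 10), an exact k×k
linear-assignment reduction, and seeded Cross-Entropy Monte Carlo for large
panels.  Input lists with tied top genes are handled by aggregating every
tie concretization and keeping the lowest-objective result.

## Worked example

Aggregate six published stability rankings of nine candidate genes in goat
liver (shipped as a fixture; the CSV layout is one column per program, rows =
rank positions 1..9), treating the geNorm top pair as tied:

```sh
python - <<'PY'
from refrank.rank_aggregation import write_rank_csv
from refrank.synthetic_data import tables4to8_fixture
write_rank_csv(tables4to8_fixture("liver"), "liver_ranks.csv")
PY
refrank aggregate liver_ranks.csv --method brute_force --tie-top2 genorm
```

prints

```
 rank     gene
    1   HSP-90
    2     ACAC
    3 18s rRNA
    4     ALAS
    5     HMBS
    6     ACTB
    7      B2M
    8    RPS18
    9    GAPDH
objective: 32
```

HSP-90 is the consensus best reference gene for liver and GAPDH the worst;
the objective is the total footrule distance from the consensus to the six
input lists (here after choosing the better of the two geNorm tie variants).

The same end to end from raw data: simulate a study-like Ct table (9 genes ×
4 tissues × 2 treatments × 3 biological × 3 technical replicates), then
analyze it per tissue and pooled:

```sh
refrank simulate --seed 5 --out sim.csv
refrank analyze --input sim.csv --dialect long --output-dir out --seed 5
```

Each group's report is a table with one column per stability method plus a
`Consensus` column, written under `out/<group>/` together with per-method
scores, the rank matrix, the consensus JSON (ordering, objective, per-list
distances) and a run manifest.

## Layout

* `refrank.ct_data` — Ct table model, CSV I/O (wide/long), replicate
  collapsing, efficiencies, quantities, normalization factors
* `refrank.stability_metrics` — the four stability algorithms and the
  optimal-reference-count analysis
* `refrank.rank_aggregation` — footrule distance, the three consensus
  solvers, tie resolution, rank-matrix CSV I/O
* `refrank.pipeline` — study orchestration, YAML config, report writing
* `refrank.synthetic_data` — the seeded Ct simulator and embedded benchmark
  fixtures
* `refrank.cli` — `refrank analyze | aggregate | simulate`

See `docs/methods.md` for the underlying models, parameter choices and known
limitations.
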