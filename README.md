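# pulserate

Genome-wide RNA synthesis and decay rates from a **single-timepoint 4sU
metabolic-labeling experiment**, with the downstream stability statistics used
to relate decay rates to gene features, and a fully ground-truthed synthetic
experiment generator so every stage is testable without external data.

## Who this is for

Groups measuring RNA kinetics in intact tissue (for example cultured
*Drosophila* larval brains) cannot run long pulse–chase time courses: ex vivo
time is limited and sampling is destructive.  Instead, a short pulse of
4-thiouridine (4sU) labels nascent RNA; the labeled (streptavidin pull-down)
and total RNA fractions are sequenced from the *same* sample, and kinetic
rates are inferred under a steady-state model.  `pulserate` implements that
inference, its quality controls, and the statistics linking stability to
transcription-factor status, cell-type specificity and H3K27me3 silencing.

## Model

Per gene, first-order kinetics with synthesis rate α (TPM/min), processing
rate k_p (1/min) and decay rate k_d (1/min):

    dP/dt = α − k_p·P          dM/dt = k_p·P − k_d·M

At steady state P\* = α/k_p and M\* = α/k_d.  A pulse of length t fills the
labeled pools according to the closed-form solution with zero initial labeled
RNA; for a short pulse the total labeled signal ≈ α·t, so

    α  = s · (labeled TPM) / t
    k_d = α / (total TPM − premature TPM)        half-life = ln2 / k_d
    k_p = α / premature TPM

where premature = intronic signal, total = exonic signal, and s converts
pull-down TPM into total-library TPM units (estimated from thiolated
spike-ins).  An `exact` mode inverts the full closed-form pulse solution by
fixed-point iteration instead of the linear approximation.

Pull-down purification carries over unlabeled RNA at roughly 1:100; a
carryover ratio r bounds the longest resolvable half-life at ln2·t/r
(1386 min for r = 0.01, t = 20 min), so reported half-lives are capped at
1000 min.

Downstream, log10 decay rates are winsorized at the top/bottom 1% and
regressed on three binary gene features — TF (transcription factor),
me3 (extended H3K27me3: peaks upstream, over the gene body, and downstream),
CTS (cell-type-specific: enriched in one cell type with p < 0.05 and ≥2-fold)
— with or without interaction terms (β0…β7), and the fits are repeated on
stratified bootstrap resamples that draw equally from each of the 8
nonoverlapping feature combinations.

## Worked example

```python
import numpy as np
from pulserate import SimulationConfig, simulate_experiment, estimate_rates

config = SimulationConfig(n_genes=2000, seed=4)   # 82-min median half-life,
sim = simulate_experiment(config)                 # 20-min pulse, 1:100 carryover
rates, info = estimate_rates(sim.counts, sim.spike_table)

print(f"genes with rates: {len(rates)}")
print(f"scale factor s:   {info['scale']:.4f}")
print(f"median half-life: {rates['half_life'].median():.1f} min")
print(f"sigma log10 decay: {np.log10(rates['decay']).std(ddof=1):.3f}")
```

prints

```
genes with rates: 1998
scale factor s:   0.1382
median half-life: 78.5 min
sigma log10 decay: 0.411
```

The generator's true median half-life is 82 min with a log10 decay spread of
0.44: the short-pulse estimator recovers the median to within a few minutes
(labeled RNA already decays during the pulse, a small downward bias on
half-lives) and slightly compresses the stable tail because carryover puts a
floor under apparent decay rates.  Estimated and true log10 decay rates
correlate at r ≈ 0.97 on this fixture.

The same stages are available from the shell:

```
pulserate simulate --outdir fixture --n-genes 2000 --seed 4
pulserate rates --counts fixture/counts.tsv --libraries fixture/libraries.tsv \
    --spike-ins fixture/spike_ins.tsv --out rates.tsv
pulserate all --config run.yaml        # full pipeline incl. annotation + stats
```

## Layout

* `pulserate.simulate` — kinetic parameter sampling, closed-form labeled
  pools, library/count simulation, fixture writer.
* `pulserate.quantify` — count/TPM tables, expression filter, TPM
  recomputation, premature/mature split.
* `pulserate.rates` — scale estimation, synthesis/processing/decay rates,
  specificity cap, CV propagation, steady-state check.
* `pulserate.annotate` — TF lists, CTS classification, H3K27me3 peak-to-gene
  categories, nonoverlapping feature groups.
* `pulserate.stats` — stability percentiles, Mann–Whitney group tests,
  Fisher/odds-ratio enrichment, winsorized OLS, stratified bootstrap,
  per-feature mean changes.
* `pulserate.derepression` — total-vs-nascent ratio shift after knockdown.
* `pulserate.pipeline` / `pulserate.cli` — orchestration and subcommands.

See `docs/methods.md` for modeling assumptions, parameter defaults and known
limitations.
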