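# routesim

Spatially explicit forward-in-time simulation of multi-allelic balancing
selection, and ABC inference of how modern humans colonized East Asia.

## The problem

Northern and Southern East Asian populations differ sharply in their
genetic makeup, including at the HLA immune genes, whose allelic
*lineages* show a continuous north–south gradient and — unusually —
*higher* gene diversity in the north. Did modern humans enter the region
by a single southern route, or by two routes on both sides of the
Himalayas? Because HLA genes also evolve under balancing selection
(heterozygote advantage), demography and selection must be disentangled
jointly. `routesim` is for population geneticists who want to reproduce
and extend this kind of analysis: it simulates lineage frequencies of one
HLA locus on a zoned deme lattice under three colonization scenarios —

* **Southern-origin** — one expansion from the southwest; the 29–33°N
  band (Qinling–Huaihe / Yangtze) is a complete barrier until `t1`;
* **Pincer** — two expansions (southwest and northwest) from a common
  ancestral source, same barrier until `t1`;
* **Overlapping** — two expansions (southeast and northeast); an ancient
  barrier in the 41–45°N band until `t1`, and a later partial barrier
  (0.1 m) in the 29–33°N band from `t2` — long-lasting north–south
  gene flow in between;

with logistic growth (`r`, `K`), stepping-stone migration (`m`),
balancing selection (`s`; symmetric, latitudinal, or negative
frequency-dependent) and Wright–Fisher drift, all parameters drawn from
uniform priors. Simulated samples of 19 populations are summarised by 12
statistics (lineage counts, Nei gene diversity overall and per group, the
diversity–latitude correlation `R_H-lat`, and AMOVA `F_ST`/`F_CT`/`F_SC`)
and compared with the published observed vectors for HLA−A, −B and −DRB1
by Approximate Bayesian Computation: δ-retention model choice, Bayes
factors `B_AB = fM_A(s_obs)/fM_B(s_obs)`, PLS dimension reduction, ABC-GLM
posteriors with 95% HPD intervals, and posterior-quantile calibration.

See `docs/methods.md` for the full model description and numerical
conventions.

## Worked example

```python
import routesim as rs

dememap = rs.build_map(rs.SMALL_MAP_CONFIG)      # 12x9 desk-scale lattice
sites = rs.default_sample_spec(dememap)          # 19-population panel

params = rs.draw_parameters("overlapping", seed=7)
state = rs.run_simulation(dememap, params, seed=7)
samples = rs.sample_populations(state, sites, seed=7)
sv = rs.compute_stats(samples)
print(f"A={params.A} s={params.s:.4f} T={rs.admixture_time(params)}")
print(f"M_A={sv['M_A']:.2f} M_H={sv['M_H']:.3f} "
      f"R_H_lat={sv['R_H_lat']:+.2f} F_ST={sv['F_ST']:.4f}")
```

prints

```
A=43 s=0.0070 T=2436
M_A=27.79 M_H=0.941 R_H_lat=+0.89 F_ST=0.0237
```

— one prior draw of the Overlapping scenario: 43 ancestral lineages under
moderate balancing selection with ~2,400 generations (~60,000 years) of
north–south exchange end up with ~27.8 lineages per population sample,
high gene diversity, a strongly *positive* diversity–latitude correlation
(as observed in real East Asian data, where the Southern-origin model
mostly produces a negative one), and modest differentiation among
populations.

The same machinery scales up through `routesim` subcommands
(`make-fixtures`, `simulate`, `sumstats`, `abc-choice`, `abc-estimate`,
`abc-validate`, `pipeline`), e.g.

```sh
routesim simulate --scenario southern --n 100 --seed 1 --out ref_south.tsv
routesim abc-choice --ref ref_south.tsv --ref ref_pincer.tsv \
    --ref ref_over.tsv --obs HLA-A --delta 0.005
```

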