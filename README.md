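# invaroute

Inference of biological invasion routes from dual genetic markers
(microsatellites + mtDNA), built around coalescent simulation of competing
introduction scenarios and Approximate Bayesian Computation (ABC).

The package models a study design with one large native source population,
three sampled introduced populations and one unsampled ("ghost")
population.  Two competing histories are built in:

* **scenario1** — two simultaneous independent introductions from the
  native range (ghostNZ and Cal) at time `t3`; at `t2` Cal founds a second
  introduced population (inva2) and an admixed population (NZ2) is founded
  from ghostNZ and Cal with proportion `r`.
* **scenario2** — a serial chain: native → ghostNZ (`t3`) → Cal (`t2`) →
  inva2 (`t1`), with the NZ2 admixture at `t1`.

Every introduction starts from 25 diploid founders held for a 5-generation
bottleneck before reaching the stable introduced size (1000); the native
size is 5000.  Time is measured in generations before present.

## Modules

| module | contents |
| --- | --- |
| `invaroute.demography` | scenario/prior data model, validation, parameter sampling, YAML config round trip |
| `invaroute.coalsim` | structured-coalescent genealogy simulation (founding, admixture, bottlenecks), stepwise-mutation microsatellites, HKY sequences (invariant sites + gamma rates) |
| `invaroute.popstats` | allelic richness (rarefaction), heterozygosities, Weir–Cockerham theta, sequence diversity, permutation group tests, the fixed-order ABC summary vector |
| `invaroute.neutrality` | Fu's Fs (Ewens sampling formula, log-space Stirling numbers), Ramos-Onsins & Rozas R2, coalescent-resampling p-values, mismatch distributions and a sudden-expansion least-squares fit |
| `invaroute.abc` | reference tables, standardized rejection, logistic model choice on the closest 1%, local-linear posterior adjustment (logit scale, Epanechnikov weights) |
| `invaroute.synthdata_io` | Genepop/FASTA readers and writers, seeded pseudo-observed bundles, the end-to-end pipeline |

## Command line

```bash
# generate a pseudo-observed dataset at the default truth values
invaroute synth --seed 1 --out po/

# summary statistics of a dataset
invaroute sumstats --genepop po/microsats.genepop.txt \
    --fasta frag600 po/frag600.fasta --fasta frag400 po/frag400.fasta \
    --out observed.json

# ABC reference table, model choice, estimation
invaroute simulate-table --scenario scenario1 --n-sims 20000 --seed 2 --out ref1.tsv
invaroute simulate-table --scenario scenario2 --n-sims 20000 --seed 3 --out ref2.tsv
invaroute model-choice --table ref1.tsv --table ref2.tsv \
    --observed observed.json --out probs.json
invaroute estimate --table ref1.tsv --observed observed.json \
    --scenario scenario1 --out posterior.json

# neutrality statistics and mismatch fits per population
invaroute neutrality --fasta frag600 po/frag600.fasta \
    --fasta frag400 po/frag400.fasta --seed 4 --out neutrality.json

# diversity table (Na, A, Ho, Hs, h, H, theta_pi, S per population)
invaroute diversity --genepop po/microsats.genepop.txt \
    --fasta frag600 po/frag600.fasta --fasta frag400 po/frag400.fasta \
    --out diversity.tsv

# the full chain from one YAML config
invaroute run --config config.yaml --out out/
```

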