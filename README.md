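# tetradrive

Simulation, exact enumeration and inference for **spore-killer meiotic drive**
in fungal ordered tetrads, modelled on the *Podospora anserina* Spok system.

## The problem

Spore killers are selfish genetic elements that cheat Mendelian segregation:
in a cross between a killer-carrying strain and a sensitive strain, the
ascospores that did not inherit the killer die inside the ascus, so the
element reaches far more than 50% of the surviving progeny. In *P. anserina*
each ascus packages the eight post-meiotic nuclei into four **binucleate**
spores, two per first-division (MI) pole. Whether a heterozygous locus
separates its alleles at meiosis I (**FDS**, no centromere-locus crossover)
or meiosis II (**SDS**) therefore decides the fate of the whole ascus:

* **FDS** asci — each spore is homokaryotic; the two spores lacking the
  killer die, leaving a diagnostic *2-spored* ascus;
* **SDS** asci — every spore is heterokaryotic and a single resistant
  nucleus rescues its spore, so all four survive.

The fraction of 2-spored asci hence equals `1 − s`, where `s` is the SDS
frequency of the killer locus, and maps the element relative to its
centromere (`d ≈ s/2 × 100` cM). Killing itself follows a toxin–antitoxin
("distorter/responder") rule: every active distorter in the zygote poisons
the ascus and a spore survives only if some allele it carries *covers* every
such distorter. Both activities can live on one allele, be decoupled
(responder-only resistant alleles; killers whose responder must be
trans-activated by a wild-type copy), or interact across paralogues — the
*Spok1*-type element covers *Spok2*-type killing but not vice versa.

`tetradrive` implements this model end to end:

* `tetradrive.genetics` — ordered-tetrad meiosis with per-locus FDS/SDS
  probabilities (plus an optional mechanistic Poisson-crossover mode with
  the classical closed form `s(x) = (2/3)(1 − e^(−3x))`), binucleate-tetrad
  and uninucleate-octad spore packaging;
* `tetradrive.killing` — the distorter/responder rule engine with
  resistance epistasis and trans-activation;
* `tetradrive.simulate` / `tetradrive.exact` — Monte Carlo cross
  simulation and the brute-force exact enumerator used as its oracle;
* `tetradrive.inference` — SDS/centromere-distance estimation with exact
  confidence intervals, marker transmission-ratio scans (exact binomial
  tests, Benjamini–Hochberg), goodness-of-fit tests;
* `tetradrive.introgression` — recurrent backcrossing with selection for
  the driver, tracking residual donor segments;
* `tetradrive.strains` — the full strain library and cross registry of the
  modelled system (wild isolates, deletion strains, pigment-locus
  insertions, tagged and mutant alleles), plus synthetic marker-genotype
  datasets for testing the scan.

## Worked example

Exact prediction for the classic sensitive × killer cross (*Spok1*
heterozygous at SDS 10%, *Spok2* heterozygous at SDS 60% but masked by
*Spok1* resistance):

```text
$ tetradrive enumerate --cross SxT
cross    class  n_viable  n_pigmented  probability  percent
  SxT 2-spored         2            2          0.9     90.0
  SxT 4-spored         4            4          0.1     10.0
```

Ninety percent of asci are 2-spored: only *Spok1*'s SDS frequency shows,
because every surviving spore carries *Spok1* and is thereby also protected
from *Spok2*. Simulating the same cross reproduces the prediction and lets
you inspect survivors:

```text
$ tetradrive simulate --cross registry:SxT --n-asci 10000 --seed 1 --out out/
SxT: wrote out/ascus_counts.tsv (10000 asci)
$ head -3 out/ascus_counts.tsv
cross	class	n_viable	n_pigmented	count	n_asci	seed
SxT	2-spored	2	2	8967	10000	1
SxT	4-spored	4	4	1033	10000	1
```

Among surviving spores that are homokaryotic at the *Spok2* locus the two
alleles segregate 50:50 — the element's own drive is fully masked. Turning
ascus counts back into a map position:

```text
$ tetradrive estimate --two 9000 --four 1000
s_hat=0.1000 ci=[0.0942, 0.1060] n=10000 map_distance=5.00 cM
```

i.e. an SDS frequency of 10% with an exact 95% CI, placing the killer about
5 cM from its centromere. `tetradrive scan` runs the transmission-ratio
scan that localises a driver from survivor genotypes, and
`tetradrive backcross` simulates the recurrent-backcross construction of a
near-isogenic killer strain. The same operations are available as plain
library calls (`enumerate_cross`, `simulate_cross`, `estimate_sds`,
`transmission_scan`, `simulate_backcross_program`).

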