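# fishauth

DNA-based authentication of white-fish retail products: does the fish in
the packet match the species on the label?

The package re-implements, as a tested pipeline, a two-assay audit of
supermarket white fish (cod, haddock, pollock, hake, whiting):

1. **Endpoint real-time PCR.** Species-specific TaqMan probes for
   Atlantic cod (*Gadus morhua*) and haddock (*Melanogrammus
   aeglefinus*) are read on two dye layers of a 96-well plate. A well is
   positive on a dye when its cycle-40 ΔRn exceeds the plate's
   no-template-control threshold
   `z*M = M + 3.89·SD + C`, where `M` and `SD` are the mean and standard
   deviation of the NTC endpoint ΔRn for that dye layer, 3.89 is the
   one-tailed normal quantile for 99.999% confidence, and `C = 0.3`
   absorbs spectral bleed between dye layers. The two probe calls
   combine into COD / HADDOCK / INCONCLUSIVE (both) / NEGATIVE (neither).
2. **COI barcoding.** Each product is sequenced twice (independent
   extractions) for the ~655 bp 5′ COI barcode and assigned to the
   reference species with the highest pairwise identity; an
   identification requires ≥ 99.5% identity. Congener pairs with
   identical barcodes (*G. macrocephalus*/*G. ogac*,
   *G. chalcogrammus*/*G. finnmarchica*) form single assignable groups.
   A sub-threshold best hit whose runner-up is **not** the best hit's
   nearest relative indicates DNA from more than one species (a mixed
   product), as do disagreeing replicate extractions.
3. **Concordance.** A rule table maps (label, catch area) to acceptable
   genetic groups — generic "cod" accepts either cod species, cod sold
   as "Atlantic" only *G. morhua* — and mislabelling rates are reported
   overall, per labelled species and per processing level (1 fresh
   fillet … 5 fishcake), with exact binomial confidence intervals and an
   extrapolation of the haddock-declared-but-cod rate to excess landings
   in tonnes.

A neighbour-joining tree (Kimura 2-parameter distances, nonparametric
bootstrap) is built from scratch for visual confirmation of
assignments, and a synthetic-data module emulates the whole survey —
gadoid-like reference panel with controlled divergences, error-bearing
replicate sequences, chimeric products, plate fluorescence — so every
stage is testable offline. The survey's mislabelled-product table is
shipped as a packaged fixture.

## Worked example

Simulate a 371-sample survey with the study's label mix, a planted
mislabelling rate of 5.66% and mixed-species products, then run the
full pipeline on it:

```python
from fishauth.synthetic import SimulationConfig, simulate_study
from fishauth.pipeline import run_synthetic_study
from fishauth.concordance import binomial_ci

cfg = SimulationConfig(seed=42)
study = simulate_study(cfg)
res = run_synthetic_study(cfg, study=study)

st = res.summary.overall
print("planted:", int(study.truth.planted_mislabel.sum()))
print(f"estimated: {st.n_mislabelled}/{st.n} = {st.pct}%")
lo, hi = binomial_ci(st.n_mislabelled, st.n)
print(f"95% CI: [{100*lo:.2f}%, {100*hi:.2f}%]")
```

prints

```
planted: 20
estimated: 20/371 = 5.39%
95% CI: [3.32%, 8.20%]
```

— the pipeline recovered every planted mislabelled product (20 of 371
in this realisation; the binomial CI covers the planted rate).

The packaged survey fixture reproduces the study's published rate
table:

```sh
$ fishauth verify
overall                  computed   5.660  printed   5.66  ok
cod                      computed   5.028  printed   5.03  ok
atlantic_cod_as_pacific  computed  10.526  printed   10.5  ok
haddock                  computed   5.806  printed   5.81  ok
...
all checks passed
```

Other CLI entry points: `fishauth simulate`, `fishauth qpcr-call`,
`fishauth barcode-assign`, `fishauth tree`, `fishauth report` (see
`--help` for each).

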