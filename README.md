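# alleleclock

Detecting selection from **allelic age** rather than allele frequency.

A deleterious (or beneficial) allele segregating at a given population
frequency is, on average, *younger* than a neutral allele at the same
frequency — it was unlikely to get there, and when it did, it got there
fast.  `alleleclock` turns that classical prediction into a working
analysis stack for phased sequencing panels:

* **Diffusion theory** — mean allelic age and sojourn-time densities
  conditional on current frequency x under genic selection (γ = 2Ns,
  constant N, time in 2N generations).  The sojourn density is the
  Green's function of the Wright–Fisher diffusion, time-reversed and
  conditioned on the allele currently segregating; for γ = 0 it is flat
  below x and integrates to −2·[x/(1−x)]·ln x.
* **Forward Wright–Fisher simulation** — individual-based, with selection,
  recombination, and demographic change (expansion, bottleneck), recording
  the true origin generation of every mutation so age conditional on
  frequency is directly observable.
* **The Neighborhood-based Clock (NC)** — for an index variant on a phased
  panel, the base-10 log of the summed upstream + downstream physical
  distances to the nearest signal of a younger event: a four-gamete
  recombination pattern, or a *fully linked rarer* variant (carriers a
  strict subset of the index variant's carriers).  Younger alleles sit on
  longer intact haplotypes and get larger NC.
* **Category statistics** — site-frequency spectra by functional category,
  the excess-of-rare deleterious-fraction estimate with the synonymous
  spectrum as the neutral expectation, per-MAC Mann–Whitney comparisons
  with bootstrap CIs, Stouffer meta-analysis across MAC classes, Spearman
  correlation with damage scores, and population-private fractions.
* **Synthetic data** — phased panels with known truth (age, selection
  class, labels) for end-to-end validation, since the motivating trio
  panel is access-restricted.

Intended users: population geneticists analysing phased panels with
functional annotations, and anyone who needs a tested reference
implementation of age-conditional sojourn theory or of the NC statistic.

## Worked example

```python
import numpy as np
import alleleclock as ac
from alleleclock import synth

# theory: a 3% allele under strong purifying selection is far younger
sel0, sel10 = ac.SelectionParams(0.0), ac.SelectionParams(-10.0)
print(round(ac.mean_age(0.03, sel0), 4), round(ac.mean_age(0.03, sel10), 4))
# 0.2169 0.0927        <- mean ages in units of 2N generations

# synthetic panel: 188 phased haplotypes, 70% of new mutations at gamma=-10
cfg = synth.SyntheticConfig(seed=5, category_probabilities={
    "neutral": {"synonymous": 1.0}, "selected": {"probably_damaging": 1.0}})
panel, truth = synth.generate_panel(cfg)          # a few minutes
synth.assign_categories(panel, truth, cfg)
nc = ac.nc_scan(panel, mac_range=(2, 6))
out = ac.compare_nc(nc, baseline_category="synonymous", seed=99)
print(out[out.category == "probably_damaging"][["mac", "n", "effect_size", "p"]])
```

On this seed the comparison table shows positive effect sizes (selected
variants shifted toward larger NC, i.e. younger) at every minor allele
count 2–6 and a combined Stouffer p-value of about 2×10⁻⁴ — the pipeline
recovers the generative age signal from haplotype data alone.

The same steps are available from the shell:

```bash
allele-clock theory --x 0.03 --gamma -10 --grid 2000 --out profile.tsv
allele-clock synth --seed 7 --out-prefix demo
allele-clock nc --vcf demo.vcf --annotations demo.annotations.tsv \
    --ancestral demo.ancestral.tsv --mac 2:6 --out nc.tsv
allele-clock compare --nc nc.tsv --baseline synonymous --seed 7 --out table.tsv
```

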