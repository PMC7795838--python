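# sagisou

Quantitative morphometrics and microsatellite population genetics for the
egret orchid *Habenaria radiata* ("sagisou"), a near-threatened wetland
orchid whose lip (labellum) resembles a flying egret.  The package is aimed
at researchers characterising natural orchid populations from two kinds of
evidence:

* **Lip shape** — vector outlines of the lip with landmark annotations are
  reduced to seven measurements (area, perimeter, body length, body width,
  wing length, body–wing angle, serration number) plus the **dissection
  index** DI = perimeter/√area of the left wing, a dimensionless complexity
  measure bounded below by 2√π ≈ 3.545 (a circle).  Six traits are scaled by
  fixed maxima (DI/40, BL/30, BW/10, WL/40, A/90, Se/50) into radar-chart
  profiles comparable across populations.
* **SSR genotypes** — diploid microsatellite tables (Genepop or STRUCTURE
  text) are summarised per population as N, expected heterozygosity
  *He* (Nei's unbiased gene diversity, (2n/(2n−1))(1−Σp²)), observed
  heterozygosity *Ho*, and the fixation index **F = 1 − Ho/He** (positive
  under inbreeding, negative under the heterozygote excess typical of
  bulb-propagated clones), with conditional exact Hardy–Weinberg tests,
  a multi-locus permutation test for F, and Chakraborty null-allele
  estimates.  Between-unit structure is analysed with Nei's standard
  genetic distance D = −ln(J_XY/√(J_X·J_Y)), neighbor-joining trees with
  locus-bootstrap supports, and a STRUCTURE-style admixture Gibbs sampler
  with Evanno ΔK model choice.

Because raw genotypes and flower images of the original field survey are
not public, the package ships a first-class **synthetic-data module** that
generates parametric egret-lip contours and SSR datasets with known ground
truth (allele spectra, F_IS, admixture proportions, clonal founders), so
every stage is verifiable by parameter recovery and oracle equivalence.

## Worked example

```python
import numpy as np
from sagisou.synthetic import LipShapeParams, PopSimParams, \
    generate_lip_contour, simulate_genotypes
from sagisou.morphometrics import measure_lip, normalize_profile
from sagisou.popgen import population_table

# a lip with a 12 mm body, 15 mm wings at 80 degrees, 25 marginal teeth
ann, truth = generate_lip_contour(LipShapeParams())
m = measure_lip(ann)
print(m.body_length, m.wing_length, m.angle, m.serration_number)
# 12.000 15.000 80.000 25
print(round(m.dissection_index, 3), np.round(normalize_profile(m).as_array(), 3))
# 6.882 [0.172 0.4   0.4   0.375 0.889 0.5  ]

# one inbred population: F_IS = 0.2, 200 plants, 20 SSR loci
ds, _ = simulate_genotypes(PopSimParams(
    n_populations=1, n_individuals_per_pop=(200,), n_loci=20,
    f_is_per_pop=(0.2,), seed=1))
print(population_table(ds, reps=199, seed=0).round(4))
#   population    n      he      ho       f    f_p  significant
# 0       PopA  200  0.7181  0.5915  0.1763  0.005         True
```

The measured factors reproduce the generating parameters exactly (the
serration count via prominence peak detection on the wing margin), and the
recovered fixation index 0.176 sits within sampling error of the simulated
F_IS = 0.2, flagged as a significant deviation from Hardy–Weinberg
expectations by the allele-permutation test.

The same stages are available from the shell:

```sh
sagisou simulate-genotypes --pops 8 --loci 21 --seed 1 --genepop hab.gen
sagisou popgen-stats --genepop hab.gen --reps 1999 --seed 1 --out table.csv
sagisou nei-nj --genepop hab.gen --unit individual --bootstrap 1000 \
    --seed 1 --newick tree.nwk --cap 10
sagisou run-all --outdir run1 --seed 1
```

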