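# fibroquant

Phenotypic digital-pathology quantification of liver fibrosis from
collagen-stained biopsy images.

Histological staging systems (METAVIR/NASH-CRN F-stages, the Laennec
4A/4B/4C cirrhosis sub-stages, the Beijing progressive/indeterminate/
regressive patterns) are categorical and sensitive to where the needle
sampled the liver.  The classical continuous alternative, the collagen
proportionate area

```
CPA = 100 · |collagen pixels| / |tissue pixels|
```

is a single area ratio and inherits the full preanalytical variability of
staining and sectioning.  `fibroquant` implements the phenotypic
alternative: segment every collagen fibre, quantify it in three trait
layers — collagen deposition (12 traits), fibre morphometry (13 traits)
and fibrosis architecture (7 GLCM texture traits) — describe each trait's
within-biopsy distribution by five histogram statistics (mean, median,
SD, skewness, kurtosis), and call each such statistic a *quantitative
fibrosis trait* (qFT).  A continuous severity biomarker is then a
normalised, equi-weighted linear combination of the *principal* qFTs:

```
score(x) = lo + (hi − lo) · (1/k) Σ_j  clip[(x_j − a_j)/(b_j − a_j)]^(±)
```

where a qFT `j` is principal if its group means differ by ≥ 20 %
(relative) with a significant two-group test between two severity
phenotypes, `(a_j, b_j)` are the fitting cohort's 2.5th/97.5th
percentiles, the sign flips qFTs that decrease with severity, and
`(lo, hi)` is the output scale (default 0–10).  Intra-liver sampling
variability of any biomarker is summarised per liver by the coefficient
of variation `CoV = 100 · σ/μ` over that liver's biopsies, and
classification performance by the rank-estimator AUROC with a stratified
bootstrap CI.

The package is aimed at researchers who want a transparent, fully
re-runnable counterpart of this class of pipeline: every stage — colour
(stain-vector) normalisation, tissue detection, 50 µm ROI erosion,
artefact-fragment removal, collagen segmentation, skeleton-based fibre
branching, assembled/fine fibre classing (branch cutoff 21), qFT
extraction, composite-score fitting and cohort analysis — is an ordinary
Python function, and a synthetic-histology generator provides stained
biopsy images with ground-truth masks so the whole chain can be validated
at desk scale.

## Worked example

```python
from fibroquant import PhenotypeParams, generate_biopsy, process_biopsy
from fibroquant.config import PipelineConfig
from fibroquant.traits import GLCMSpec

params = PhenotypeParams(severity=0.5, n_fragments=2, seed=4)
image, truth = generate_biopsy(params, width_px=768, height_px=320, mpp=2.0)

cfg = PipelineConfig(glcm=GLCMSpec(tile_width_px=64, tile_height_px=64))
result = process_biopsy(image, cfg)
print(f"fragments: {result.tissue.n_fragments}")
print(f"fibres: {len(result.fibres)}  "
      f"(assembled: {result.qft.n_assembled}, fine: {result.qft.n_fine})")
print(f"CPA: {result.cpa_percent:.1f}%")
print(f"qFT parameters: {len(result.qft)}")
```

prints

```
fragments: 2
fibres: 77  (assembled: 1, fine: 76)
CPA: 39.1%
qFT parameters: 340
```

i.e. the two planted tissue fragments are recovered, the septa network
forms one highly branched ("assembled", > 21 skeleton branch points)
fibre alongside 76 fine fibrils, about 39 % of the analysed tissue is
collagen in this mid-severity cirrhotic rendering, and the biopsy is
described by 340 named qFTs
(`<layer>.<trait>.<population>.<statistic>`).

The same stages are available from the shell:

```bash
fibroquant generate --seed 7 --out cohort/ --n-livers 4 --biopsies-per-liver 5
fibroquant quantify --out results/ cohort/cohort_truth.csv
fibroquant cov      --out cov/ results/biopsy_records.csv --metric cpa_percent
```

## Layout

| module | contents |
| --- | --- |
| `fibroquant.synthetic` | stained-biopsy generator with ground truth |
| `fibroquant.stains` | stain profiles, Beer–Lambert OD arithmetic |
| `fibroquant.preprocessing` | stain normalisation, tissue/ROI, fragment rules |
| `fibroquant.segmentation` | collagen mask, fibre objects, branch counting |
| `fibroquant.traits` | morphometry / deposition / GLCM architecture layers |
| `fibroquant.qft` | histogram statistics, qFT vectors, CPA |
| `fibroquant.composite` | principal-qFT selection, composite scores |
| `fibroquant.cohort` | CoV, summaries, AUROC, group comparisons |
| `fibroquant.pipeline`, `fibroquant.cli` | orchestration and CLI |

See `docs/methods.md` for the underlying model, parameter defaults and
known limitations.
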