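# bpeq — quantitative background parenchymal enhancement rate in breast DCE-MRI

Background parenchymal enhancement (BPE) is the contrast uptake of *normal*
fibroglandular tissue (FGT) on dynamic contrast-enhanced breast MRI. Elevated
BPE is associated with breast-cancer risk, but radiologist BI-RADS grading of
it is subjective. `bpeq` implements a fully automated, quantitative
alternative: the **background parenchymal enhancement rate**

```
BPER = Ve / Vt × 100%
```

where `Vt` is the total FGT volume of a breast and `Ve` the volume of FGT
that enhances after contrast, measured at the early (2 min), mid (4 min)
and late (6 min) post-injection phases.

The imaging pipeline has three stages, each usable on its own:

1. **Whole-breast segmentation** — skin line and chest wall are delineated
   on every axial slice as globally minimum-cost paths (dynamic programming
   on an oriented gradient cost), with a cross-slice band constraint that
   exploits the continuity of both boundaries between adjacent slices.
2. **FGT segmentation** — fuzzy c-means clustering of in-breast intensities
   with automatic selection of the number of clusters (Xie–Beni validity
   index); on fat-suppressed pre-contrast images FGT is the brightest
   cluster.
3. **Enhanced-FGT segmentation** — pre/post subtraction images are
   thresholded at `z × σ̂`, where `σ̂` is a robust (MAD) noise estimate from
   a non-enhancing reference region (air outside the skin line).

Downstream, the statistics layer reproduces the study-style risk analysis:
Mann–Whitney comparisons, nonparametric ROC curves whose area satisfies
`AUC = U/(n₁n₂)`, selection of the maximal-AUC phase per menopausal stratum,
Youden-index cutoffs, and 2×2 odds ratios with Woolf (logit) confidence
intervals.

Because no imaging data ship with the package, a **synthetic phantom
generator** builds prone-position bilateral-breast volumes (air / skin /
fat / FGT / chest wall, phase-nested enhancement, Gaussian noise) with
exact ground-truth masks and BPER, and a **cohort simulator** draws
subject-level BPER tables for the three study groups (cancer / benign /
control, pre- and postmenopausal). Every stage is tested against these
known truths.

## Worked example

```python
import bpeq

spec = bpeq.PhantomSpec(shape=(96, 96, 32), sigma_noise=5.0, seed=2)
pre, posts, truth = bpeq.generate_phantom(spec)

masks = bpeq.segment_whole_breast(pre)         # step 1: DP boundaries
fgt   = bpeq.segment_fgt(pre, masks)           # step 2: FCM, automatic k
sub   = bpeq.subtract(posts["mid"], pre)       # step 3: subtraction ...
sigma = bpeq.estimate_noise(sub, bpeq.air_reference_mask(masks))
enh   = bpeq.threshold_enhanced(sub, fgt["left"], sigma, z=3.0)
res   = bpeq.compute_bper(fgt["left"], enh, spec.spacing)
print(f"BPER {res.bper:.2f}%  (truth {truth.true_bper['mid']['left']:.2f}%)")
```

prints

```
BPER 40.07%  (truth 40.00%)
```

i.e. at 5% image noise the estimated mid-phase BPER of the left breast is
within a tenth of a percentage point of the value the phantom was built
with. `examples/` contains one short script per capability (phantom,
boundary delineation, full measurement, cohort analysis, published-table
reproduction); `examples/published_tables.py` recomputes, from the study's
printed 2×2 counts, odds ratios of 4.1 and 4.6 (cancer vs control, pre-/
postmenopausal) and 2.6 and 2.8 (cancer vs benign) — several-fold higher
odds of cancer for women at or above the BPER cutoff — and confirms the
discriminative phase is mid (4 min) before menopause and early (2 min)
after.

A thin CLI mirrors the library: `bpeq simulate | segment-breast |
segment-fgt | segment-enhanced | bper | analyze | run` (see `--help`).
Volumes are NIfTI with axis 0 anterior→posterior (prone), axis 1
subject-right→subject-left, axis 2 inferior→superior.

## Layout

- `src/bpeq/` — `phantom`, `breast`, `fgt`, `enhancement`, `bper`,
  `stats`, `pipeline`, `config`, `volume`, `cli`
- `tests/` — unit, property and acceptance tests (pytest + hypothesis)
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — models, assumptions, parameter choices, limitations
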