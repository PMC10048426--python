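# grainscan

Automated quality assessment of milled rice from tray images: segment
individual grains out of a scene, measure each grain's geometry, color and
texture, classify its variety with a configurable machine-learning bench,
and convert the predicted variety mix of a sample into price factors that
expose adulteration (cheap grains blended into a premium sample).

The package is aimed at computer-vision / food-quality practitioners who
work with low-cost top-down imaging rigs: many mostly non-touching grains
photographed against a dark-blue background. Because no public image
dataset accompanies this acquisition style, a seeded synthetic scene
generator with pixel-exact ground truth is a first-class component — every
downstream stage is testable end to end without real photographs.

## Method

**Segmentation.** Scene → grains via the classic marker-based watershed
recipe: 5×5 median filter per RGB channel (removes salt-and-pepper
reflections), luma grayscale, global Otsu threshold, 3×3 erosion to derive
one marker per grain, 8-connected marker labeling, and watershed on
inverted grayscale restricted to the foreground. Otsu's search is
implemented explicitly: with p(k) the intensity histogram, for every
candidate threshold t the class probabilities U₀, U₁ and class means m₀,
m₁ define the between-class variance

    Vb²(t) = U₀(t) · U₁(t) · (m₀(t) − m₁(t))²

and the threshold is the smallest t maximizing Vb² (the full trace is
returned for inspection). Grains that touch fuse into one watershed region;
such oversized regions (area > 1.8 × scene median) are rejected and
reported rather than mis-measured.

**Features (330 per grain).** Geometry: 18 scalars from the mask — area A,
Crofton perimeter P, equivalent diameter √(4A/π), moment-fitted ellipse
axes L and l (grain length/width), aspect ratio L/l, solidity, extent,
roundness 4πA/P², compactness P²/A, shape factor A/(L·l), eccentricity,
orientation, hull perimeter and more. Color: 48-bin histograms of R, G, B,
H, S, V over the grain's pixels (288 counts; hue rescaled to 0–255 for
uniform binning). Texture: a masked 256×256 gray-level co-occurrence
matrix at unit offsets 0°, 45°, 90°, 135°, each summarized by six Haralick
statistics — contrast Σ(i−j)²p, dissimilarity Σ|i−j|p, homogeneity
Σp/(1+|i−j|), angular second moment Σp², energy √ASM and correlation
Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ).

**Classification.** Eight scikit-learn models (logistic regression,
decision tree, random forest, MLP, and SVMs with linear / polynomial /
RBF / sigmoid kernels) evaluated under stratified k-fold cross-validation,
with impurity-based feature selection (top-59 by default), exhaustive grid
search, confusion-matrix metrics (precision, recall, F1 = 2PR/(P+R),
macro averages) and one-vs-rest ROC curves with trapezoidal AUC.

**Pricing.** With pᵢ the price/kg of variety i and L·l² its grain-volume
proxy, a mixture with per-variety counts cᵢ has per-grain price factor
(Σ pᵢLᵢlᵢ²cᵢ)/Σcᵢ. Comparing the factor computed from *predicted* counts
with that of a pure sample of the majority variety flags adulteration;
against *true* counts it yields the percent price error.

## Worked example

Train on eight synthetic varieties (40 grains each, full render → segment
→ extract pipeline), then price a 50:30 premium/cheap mixture — the
adulteration-validation protocol:

```python
from grainscan.synth import SceneSpec, DEFAULT_PROFILES
from grainscan.pipeline import dataset_feature_table, scene_feature_table
from grainscan.features import feature_matrix
from grainscan import classify, pricing

specs = [SceneSpec(grains=[(p, 40)], width=1200, height=900,
                   noise_density=0.005, min_gap=4, seed=100 + i)
         for i, p in enumerate(DEFAULT_PROFILES.values())]
train_table = dataset_feature_table(specs)
X, y, names = feature_matrix(train_table)
report = classify.cross_validate(X, y, classify.ClassifierSpec("rf", seed=0),
                                 classify.CVPlan(k=10, seed=0))

model = classify.train(classify.ClassifierSpec("rf", seed=0), X, y)
mixture = SceneSpec(grains=[(DEFAULT_PROFILES["BM"], 50),
                            (DEFAULT_PROFILES["TB"], 30)],
                    width=1200, height=900, noise_density=0.005,
                    min_gap=4, seed=777)
mix_table, _ = scene_feature_table(mixture)
Xm, truth, _ = feature_matrix(mix_table)
prices = pricing.PriceTable.from_feature_table(train_table,
                                               pricing.EXAMPLE_PRICES)
rep = pricing.adulteration_report(list(model.predict(Xm)), prices,
                                  truth=list(truth))
```

Output:

```
RF 10-fold CV: mean accuracy 0.941, macro F1 0.941
predicted counts: {'BM': 50, 'KB': 1, 'TB': 29}
actual price factor:        1845478
predicted price factor:     1847178
unadulterated price factor: 2224779
price error: 0.09%  detection rate: 1.00  adulteration flag: True
```

Reading: the forest recovers variety labels at 94% cross-validated
accuracy; on the 80-grain mixture it finds 50 premium and 30 cheap grains
(one cheap grain mislabeled as another basmati type), so the predicted
price factor lands within 0.09% of the true mixture value, while the gap
to the pure-sample factor (what an unadulterated bag would be worth)
correctly raises the adulteration flag, and every cheap grain is detected
as non-premium.

The same stages are available as a CLI — `grainscan synth | segment |
extract | train-eval | price` — each rerunnable to identical outputs given
the same seed.

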