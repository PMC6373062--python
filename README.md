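# papscreen

Automated analysis of Pap-smear (cervical cytology) images: a complete
screening pipeline that enhances bright-field micrographs, segments every
pixel into nucleus / cytoplasm / background / debris with a trainable
classifier, rejects debris with a three-phase size–shape–texture scheme,
measures 29 morphometric features per cell, selects features by simulated
annealing with a cross-validated wrapper, and classifies each cell into
seven cytological classes — superficial, intermediate and columnar (normal);
mild, moderate and severe dysplasia and carcinoma in situ (abnormal) — with
a fuzzy C-means model defuzzified through Bayes' rule. The package is aimed
at researchers building or benchmarking low-cost automated cytology
screening, and ships a synthetic-data module that reproduces the published
per-class cell statistics so every stage is testable without any image
download.

## The model in brief

A cell's membership in cluster *i* under fuzzy C-means is

```
m_ik = 1 / Σ_j (d_ik / d_jk)^(2/(q-1)),        q > 1,
```

with Euclidean distances `d` to the cluster centers and fuzzifier
`q = 1.0930` over `c = 25` clusters by default. Training points are
hard-assigned to their maximum-membership cluster; the smoothed class
composition of each cluster gives likelihoods `P(cluster | class)`, priors
are proportional to class mass, and Bayes' rule yields `P(class | cluster)`.
A new cell's class posterior is its membership vector mixed through those
per-cluster posteriors; the binary screening label collapses the seven
classes to NORMAL/ABNORMAL, and a slide is positive when any cell is
abnormal. Debris never reaches the classifier: objects outside
[625, 85 267] area units, outside the circularity band (0.15, 0.97) of
`4πA/p²`, or with outlying mean Zernike-moment magnitude are discarded, in
that order. See `docs/methods.md` for every convention and default.

## Worked example

Train the classifier on a synthetic feature table drawn from the shipped
per-class statistics and screen a second, disjoint table:

```python
from papscreen import (gen_feature_table, table_to_xy, FCMClassifier,
                       FCMClassifierConfig, confusion, metrics, binary_label,
                       CellClass)
from papscreen.feature_selection import REFERENCE_SELECTED_FEATURES

train = gen_feature_table(n_per_class=100, seed=1)
test = gen_feature_table(n_per_class=50, seed=2)
X_train, y_train, _ = table_to_xy(train, subset=REFERENCE_SELECTED_FEATURES)
X_test, y_test, _ = table_to_xy(test, subset=REFERENCE_SELECTED_FEATURES)

clf = FCMClassifier(FCMClassifierConfig(n_clusters=25, fuzzifier=1.0930,
                                        n_restarts=60), seed=0)
clf.fit(X_train, y_train)
pred = clf.predict(X_test)

truth_bin = [binary_label(CellClass(y)) for y in y_test]
pred_bin = [binary_label(CellClass(y)) for y in pred]
m = metrics(confusion(truth_bin, pred_bin)).rounded()
print(f"binary accuracy:    {m['accuracy']:.2f}%")
print(f"sensitivity:        {m['sensitivity']:.2f}%")
print(f"specificity:        {m['specificity']:.2f}%")
```

Output:

```
binary accuracy:    98.29%
sensitivity:        97.50%
specificity:        99.33%
```

Accuracy is the fraction of the 350 test cells whose NORMAL/ABNORMAL call is
correct; sensitivity is the fraction of truly abnormal (dysplastic or
malignant) cells flagged abnormal — the clinically critical rate — and
specificity the fraction of normal cells passed as normal.

The same flow is available from the shell:

```
papscreen simulate table --n-per-class 100 --seed 1 --out train.csv
papscreen fit train.csv --clusters 25 --out model.joblib
papscreen predict test.csv --model model.joblib --out pred.csv
papscreen screen pred.csv
```

plus `simulate scene`, `train-seg`, `segment`, `debris`, `select` and
`evaluate` for the image pipeline stages; the library's
`papscreen.pipeline.analyze_image` runs the whole chain on one image.

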