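# toplap

Topological featurization of protein mutation sites and gradient-boosted-tree
classification of solubility change (decrease `-`, no change `N`, increase `+`).

Given wild-type and mutant 3D structures (PDB) and a point-mutation
specification, the package builds element-specific atom clouds around the
mutation site and summarizes their multiscale shape with two families of
descriptors:

- **Persistent Laplacian (PL).** Combinatorial Hodge Laplacians of
  Vietoris-Rips complexes over an *interactive distance* (infinite between
  atoms sharing a location, Euclidean between site and environment), sampled
  over a 0-6 Å filtration grid. Dimension-0 features are statistics of the
  non-harmonic spectra (2 proteins x 13 grid values x 9 element pairs x 8
  statistics = 1872 components). Dimensions 1-2 use alpha-complex harmonic
  bars (10 selections x 2 dimensions x 7 statistics per protein; wild, mutant
  and their difference = 420 components).
- **Persistent homology (PH).** Binned dimension-0 barcode summaries of the
  same interactive-distance filtration (9 pairs x 12 bins x 2 statistics =
  216 per protein; 648 with wild, mutant and difference).

These are concatenated with a 1280-component sequence-transformer block
(pluggable provider; a deterministic stub ships for offline use) and an
optional auxiliary block, then fed to a gradient-boosted-tree classifier
evaluated with normalized multiclass metrics (CPR and generalized squared
correlation) under repeated stratified cross-validation.

All filtration machinery (Rips and alpha complexes, boundary-matrix
reduction, barcodes) is implemented in-package on top of numpy/scipy, so no
external TDA library is required.

## Layout

```
src/toplap/
  structure_io.py   PDB parsing, mutation-site labeling, element selection,
                    rASA interior/surface classification
  simplicial.py     simplicial complexes, boundary matrices, combinatorial
                    Laplacians (+ an independent entrywise construction)
  persistence.py    Rips/alpha filtrations, Laplacian spectra per snapshot,
                    persistence barcodes, the 0.1 A bar filter
  featurize.py      interactive distances, the 54 spectra sets, statistic
                    blocks, feature-vector assembly, embedding providers
  model_metrics.py  GBT training, cross-validation, confusion-matrix
                    normalization, CPR / GC2 metrics
  fixtures.py       synthetic peptide PDBs, topology point clouds, labeled
                    Gaussian datasets (deterministic, offline)
```

## CLI

```bash
# featurize one wild/mutant pair (mutation in compact chain:WT<pos>MUT form)
toplap featurize --wild wild.pdb --mutant mutant.pdb --mutation A:I283W \
    --out feats.csv

# train (labels: tab-separated sample_id, label in {-, N, +})
toplap train --features feats.csv --labels labels.tsv --out model.bin

# repeated stratified cross-validation
toplap cv --features feats.csv --labels labels.tsv --folds 10 --repeats 10 \
    --seed 0 --out report.json

# score predictions against truth
toplap eval --pred pred.tsv --truth truth.tsv
```

Reports print raw/normalized metric pairs; normalization rescales
confusion-matrix rows to equal class mass to counter class imbalance.

## Python API

```python
from toplap import featurize_pair
from toplap.model_metrics import cross_validate

fv = featurize_pair("wild.pdb", "mutant.pdb", "A:I283W", config="toplap")
fv.values      # 1872 + 420 + 1280 components
fv.schema      # named layout
```
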