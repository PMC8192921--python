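# seqmoments

Fixed-length featurization of DNA sequences and binary driver/passenger
gene classification.

Each A/C/G/T sequence is mapped to a deterministic 102-slot numeric vector:

- the encoded sequence is written row-major into a `k x k` grid
  (`k = ceil(sqrt(n))`, zero-padded) and summarized by **raw**, **central**,
  and **discrete Hahn** moments up to order 3 (10 coefficients per family);
- two 4x4 **position-relative incidence matrices** (PRIM, and RPRIM on the
  reversed sequence) are summarized by the same three moment families;
- per-base **frequency counts** and forward/reverse **position sums**
  contribute the last 12 slots.

The Hahn basis is orthonormal (built by a stable three-term recurrence with
full reorthogonalization), so the full moment transform of a grid is exactly
invertible — no sequence information is lost at the matrix level.

Feature matrices feed three configurable classifier backends (random
forest, RBF-SVM, single-hidden-layer neural network; scikit-learn) and are
evaluated with four metrics (Sn, Sp, Acc, MCC) under three protocols:
self-consistency, repeated stratified 70/30 splits, and stratified k-fold
cross-validation, plus ROC/AUC.

## Test

```bash
python -m pytest tests/
```

The suite includes independent literal-loop oracles for every moment and
incidence computation, exhaustive algebraic checks of the MCC formulation
against the product form, a Mann–Whitney oracle for AUC, property-based
tests of the conservation identities, and end-to-end behavioral checks on
synthetic data (`tests/test_acceptance.py`).

## CLI

```bash
# generate a synthetic labeled dataset (two FASTA files)
seqmoments simulate --n-pos 200 --n-neg 200 --length 300 \
    --separation 1.0 --seed 1 --out runs/sim

# build the 102-column feature matrix CSV
seqmoments featurize --pos-fasta runs/sim/positive.fasta \
    --neg-fasta runs/sim/negative.fasta --out runs/features

# run all three validation protocols with all backends
seqmoments evaluate --features runs/features/features.csv \
    --backend all --protocol all --k 10 --repeats 10 --seed 1 \
    --out runs/eval

# train and persist a single model, then score new sequences
seqmoments train --features runs/features/features.csv \
    --backend rf --seed 1 --out runs/model
seqmoments predict --model runs/model/model.joblib \
    --fasta runs/sim/positive.fasta --out runs/pred
```

Useful flags: `--mapping A=1,C=2,G=3,T=4` (base encoding),
`--prim-convention signed|absolute`, `--hahn-a/--hahn-b` (Hahn weight
parameters, default 0), `--policy strict|strip|fail-record` (handling of
non-ACGT characters). Every command writes a `run_config.json` manifest
next to its outputs; a flat `key = value` config file can be passed with
`--config` (explicit flags win).

Labels may come either from the positive/negative two-FASTA convention or
from one FASTA plus a two-column `id<TAB>label` table (`--fasta --labels`).

## Layout

| Module | Contents |
| --- | --- |
| `seqmoments.sequence_io` | FASTA I/O, validation policies, integer encoding, synthetic data generator |
| `seqmoments.moments` | grid reshape; raw/central/Hahn moments; orthonormal Hahn basis |
| `seqmoments.incidence` | PRIM/RPRIM, frequency vector, forward/reverse position sums |
| `seqmoments.features` | 102-slot vector assembly, feature-matrix CSV I/O |
| `seqmoments.models` | rf/svm/nn backends, seeded training, sidecar persistence |
| `seqmoments.evaluation` | Sn/Sp/Acc/MCC, ROC/AUC, three validation protocols |
| `seqmoments.cli` | `simulate | featurize | train | evaluate | predict` |
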