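"""Train both QSAR predictors on synthetic property rules.

The affinity regressor learns a deterministic pseudo-pIC50 (aromatic-fraction
rule) from SMILES token features; the BBB classifier learns a molecular-
weight permeability rule from Morgan fingerprints after SMOTE balancing.
"""

import numpy as np

from molrl import (FixtureSpec, OversampleSpec, classification_metrics,
                   fingerprints, make_corpus, mock_affinity_oracle,
                   regression_metrics, train_affinity, train_bbb)
from molrl.fixtures import mock_bbb_label

corpus = make_corpus(FixtureSpec(n_molecules=1500, seed=3))
rng = np.random.default_rng(0)
order = rng.permutation(len(corpus))
tr, te = order[:1200], order[1200:]

y_aff = np.array([mock_affinity_oracle(s) for s in corpus])
aff = train_affinity([corpus[i] for i in tr], y_aff[tr], seed=0)
m = regression_metrics(y_aff[te], aff.predict([corpus[i] for i in te]))
print(f"affinity QSAR held-out:  MSE {m['MSE']:.3f}  Q2 {m['Q2']:.3f}  "
      f"CCC {m['CCC']:.3f}")

y_bbb = np.array([mock_bbb_label(s) for s in corpus])
X = fingerprints(corpus)
print(f"BBB classes: {y_bbb.sum()} permeable / {len(y_bbb) - y_bbb.sum()} not"
      " (imbalanced, hence SMOTE)")
bbb = train_bbb(X[tr], y_bbb[tr], OversampleSpec("smote", seed=0), seed=0)
c = classification_metrics(y_bbb[te], bbb.predict_proba_fp(X[te]))
print(f"BBB QSAR held-out:  ACC {c['ACC']:.3f}  AUC {c['AUC']:.3f}  "
      f"Sen {c['Sen']:.3f}  Spe {c['Spe']:.3f}  MCC {c['MCC']:.3f}")
print("Q2 near 1 / AUC near 1 mean the models recovered the synthetic rules")
print("they will later use to reward the generator.")
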