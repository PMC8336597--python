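"""Sweep the objective weights and approximate the Pareto front.

Runs one short fine-tuning per affinity weight and marks which of the
resulting (affinity reward, BBB reward) operating points are non-dominated.
"""

import numpy as np

from molrl import (FixtureSpec, GeneratorConfig, RLConfig, Vocabulary,
                   build_policy, make_corpus, mock_affinity_oracle,
                   mock_bbb_oracle, train_supervised, weight_sweep)

corpus = make_corpus(FixtureSpec(n_molecules=3000, seed=0))
vocab = Vocabulary.from_corpus(corpus)
gen_cfg = GeneratorConfig(recurrent_units=64, epochs=25)
unbiased = build_policy(gen_cfg, vocab, seed=1)
train_supervised(unbiased, corpus, gen_cfg, rng=np.random.default_rng(2))

rl_cfg = RLConfig(episodes=100, batch_size=10, final_window=20)
weights = [0.0, 0.25, 0.5, 0.75, 1.0]
points = weight_sweep(unbiased, mock_affinity_oracle, mock_bbb_oracle,
                      "chebyshev", weights, rl_cfg, seed=5)

print("w_affinity  r_affinity  r_bbb   pareto")
for p in points:
    mark = "dominated" if p.dominated else "front"
    print(f"{p.weights[0]:9.2f}  {p.r_affinity:9.3f}  {p.r_bbb:6.3f}  {mark}")
print("Each row is one fine-tuning run; 'front' rows are the non-dominated")
print("trade-offs between binding affinity and BBB permeability rewards.")
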