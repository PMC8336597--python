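"""Tokenize SMILES, build a vocabulary and measure set diversity.

Builds a small synthetic corpus, shows how molecules decompose into the
tokens the generator treats as RL actions, and computes the mean pairwise
Tanimoto distance (set diversity) within the corpus.
"""

from molrl import (FixtureSpec, Vocabulary, fingerprints, make_corpus,
                   set_diversity, smiles_tokens, tanimoto, fingerprint)

corpus = make_corpus(FixtureSpec(n_molecules=200, seed=0))
vocab = Vocabulary.from_corpus(corpus)

print(f"corpus: {len(corpus)} molecules, vocabulary of {len(vocab)} tokens")
for s in corpus[:3]:
    print(f"  {s:30s} -> {smiles_tokens(s)}")

fps = fingerprints(corpus)
internal = set_diversity(fps, fps)
sim = tanimoto(fingerprint("c1ccccc1C"), fingerprint("c1ccccc1CC"))
print(f"internal diversity of the corpus: {internal:.3f}")
print(f"Tanimoto(toluene, ethylbenzene): {sim:.3f}")
print("Diversity near 1 means molecules share few fingerprint bits; a pair")
print("of close analogues scores a much higher Tanimoto similarity.")
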