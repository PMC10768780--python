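"""Encode one 41-nt window with all 14 descriptors and the 5 embedding
channels.

Prints each descriptor's dimension and a slice of its values, then trains
the k-mer embedding channels on a tiny corpus and shows the 41 x d embedding
matrix shape each recurrent branch consumes.
"""

import numpy as np

from nmsite import SynthConfig, generate_benchmark
from nmsite.descriptors import encode_all
from nmsite.embeddings import build_corpus, embed_sequence, tokenize, train_word_embedding

train, _ = generate_benchmark(SynthConfig(site_type="C", n_pos=50, neg_ratio=1, seed=0))
seq = train[0].seq
print(f"window: {seq}  (central base {seq[20]})")

vectors = encode_all(seq)
for name, vec in vectors.items():
    head = np.array2string(vec.values[:4], precision=3)
    print(f"  {name:8s} dim={vec.dim:3d}  first values {head}")

# k-mer words -> trained skip-gram vectors -> per-sequence 41 x d matrix
corpus = build_corpus([train], k=3)
model = train_word_embedding(corpus, channel="word2vec", d=16, epochs=5, seed=1)
tokens = tokenize(seq, k=3)
matrix = embed_sequence(model, tokens)
print(f"\nword2vec: vocabulary {len(model.vectors)} 3-mers, "
      f"embedding matrix {matrix.shape} (41 time steps x 16 dims)")
print("pad rows are zero:", not matrix[0].any() and not matrix[-1].any())
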