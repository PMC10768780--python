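"""Generate a synthetic Nm-site benchmark and inspect its composition.

Builds a balanced training set and a 1:10 imbalanced test set of 41-nt
windows centered on adenosine, with a consensus motif implanted around the
central site at signal strength lambda = 0.9, and prints the class counts
and the base distribution at one motif offset (where the implanted G should
dominate in positives but not negatives).
"""

from nmsite import MotifSpec, SynthConfig, generate_benchmark
from nmsite.samples import CENTER_INDEX

config = SynthConfig(site_type="A", n_pos=200, neg_ratio=10,
                     motif=MotifSpec(strength=0.9), seed=42)
train, test = generate_benchmark(config)

print(f"train: {len(train)} windows, (neg, pos) = {train.class_counts()}")
print(f"test:  {len(test)} windows, (neg, pos) = {test.class_counts()}")

offset = config.motif.offsets[0]
for label, name in ((1, "positives"), (0, "negatives")):
    bases = [s.seq[CENTER_INDEX + offset] for s in test if s.label == label]
    freq = {b: round(bases.count(b) / len(bases), 2) for b in "ACGU"}
    print(f"test {name}: base frequencies at offset {offset}: {freq}")

# The positives should show the implanted consensus base (G) at high
# frequency (expected 0.925 at lambda = 0.9, +/- sampling noise at n = 200),
# while negatives stay near the uniform 0.25.
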