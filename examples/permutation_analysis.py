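"""Ask whether stability needs allometric dispersal or just coupling.

Compares one metacommunity's leading eigenvalue against the median over
random permutations of its species' dispersal rates: if the sign rarely
changes, stability is attributable to the overall level of patch
coupling rather than to which species (e.g. top predators) move fastest.
"""

import numpy as np

import trophicmeta as tm

rng = np.random.default_rng(3)
meta = tm.generate_metacommunity(S=15, C=0.18, rng=rng, d=0.1, z=0.75)

res = tm.run_permutation_analysis(meta, n_perm=100, rng=rng)
print(f"original leading eigenvalue: {res.lambda1_original:.4f}")
print(f"median over 100 permuted-dispersal twins: {res.median_permuted:.4f}")
print(f"outcome: {res.category}")

# 'stability unaffected' means shuffling which species carries which
# dispersal rate did not flip the sign of the leading eigenvalue - the
# dispersal-rate distribution, not the body-size hierarchy behind it,
# sets the qualitative outcome.  The magnitudes do shift, which matters
# for return rates but not for the stable/unstable classification.
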