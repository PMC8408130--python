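"""Build one metacommunity and classify its linear stability.

Couples ten patch-specific copies of a single niche-model web through a
random geometric landscape with allometric dispersal (d = 0.1, z = 0.5)
and reports the local and metacommunity leading eigenvalues.
"""

import numpy as np

import trophicmeta as tm

rng = np.random.default_rng(7)
meta = tm.generate_metacommunity(S=12, C=0.18, rng=rng, d=0.1, z=0.5)

res = meta.stability()
print(f"patch leading eigenvalues: {np.round(res.local_lambda1, 3).tolist()}")
print(f"fraction of patches locally stable: {res.prop_local_stable:.1f}")
print(f"metacommunity leading eigenvalue: {res.lambda1:.4f}")
print(f"metacommunity stable: {res.metacommunity_stable}")
print(f"dispersal rates span {meta.delta.min():.3f} .. {meta.delta.max():.3f}")

# A negative metacommunity eigenvalue means the coupled system returns to
# steady state after small perturbations even though individual patches
# may be locally unstable; with z > 0 the largest-bodied consumers are the
# fastest dispersers and dominate patch coupling.
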