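"""Deduplicate a small position-matrix collection and rank motifs by DKL.

Collections pooled from several databases contain near-duplicate matrices for
the same factor (including reverse-complement copies).  We keep one
representative per redundant group — preferring experimental evidence — and
then score each survivor's conservation with the DKL index: the more negative,
the more information-rich the motif relative to a uniform background.
"""

import numpy as np

from promscan import (
    BackgroundModel,
    PositionMatrix,
    deduplicate,
    dkl_index,
    reverse_complement,
)

rng = np.random.default_rng(0)

# a sharp (conserved) motif, its reverse complement, an experimental duplicate,
# and one diffuse motif
sharp = PositionMatrix("MADS_a", np.full((8, 4), 0.02) + np.eye(4)[[1, 1, 0, 3, 3, 0, 0, 2]] * 0.92,
                       tf_family="MADS box", evidence="inferred")
sharp_rc = reverse_complement(sharp)
sharp_rc.motif_id = "MADS_a_rc"
sharp_exp = PositionMatrix("MADS_b", sharp.probs.copy(), tf_family="MADS box",
                           evidence="experimental")
diffuse = PositionMatrix("bZIP_x", rng.dirichlet([5, 5, 5, 5], size=8), tf_family="bZIP",
                         evidence="experimental")

kept, dropped = deduplicate([sharp, sharp_rc, sharp_exp, diffuse], threshold=0.8)
print(f"kept {len(kept)} of 4 motifs")
for d_id, k_id, sim in dropped:
    print(f"  dropped {d_id} (similarity {sim:.3f} to {k_id})")

bg = BackgroundModel.uniform()
for m in kept:
    print(f"  {m.motif_id}: DKL = {dkl_index(m, bg):.3f} bits")
print("The redundant MADS matrices collapse onto the experimentally derived copy;")
print("its strongly negative DKL marks a conserved, information-rich motif, while")
print("the diffuse bZIP matrix sits near zero (close to background).")
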