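"""The domain-feature pipeline on a tiny worked example.

Builds the protein-domain adjacency, the GIP kernel between domains, the
weighted association matrix, and a sparse-autoencoder embedding.
"""

import numpy as np

from dlam.domain_features import (
    build_weighted_matrix,
    encode_domain_features,
    gip_similarity,
    train_sparse_autoencoder,
)
from dlam.synthetic_data import worked_micro_example

micro = worked_micro_example()
M = micro["adjacency"]
print("adjacency (3 proteins x 2 domains):\n", M)

kernel = gip_similarity(M, alpha_prime=1.0)
print(f"kernel bandwidth alpha = {kernel.alpha}")
print(f"similarity of d1 and d2 = {kernel.similarity[0, 1]:.5f}  (= e^-1)")

W = build_weighted_matrix(M, kernel)
print("weighted matrix:\n", np.round(W, 5))
# Direct associations keep score 1; p1 gains a soft association with d2
# (0.18394 = e^-1 / 2) because d2 is similar to p1's domain d1.

rng = np.random.default_rng(0)
big = (rng.random((60, 20)) < 0.3).astype(float)
Wbig = build_weighted_matrix(big, gip_similarity(big))
sae = train_sparse_autoencoder(Wbig, hidden=8, epochs=200, seed=0)
V = encode_domain_features(sae, Wbig)
print(f"\nautoencoder on a 60x20 weighted matrix: reconstruction loss "
      f"{sae.recon_losses[0]:.4f} -> {sae.recon_losses[-1]:.4f}")
print(f"embedding shape {V.shape}, all values in [0, 1]: "
      f"{bool(np.all((V >= 0) & (V <= 1)))}")
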