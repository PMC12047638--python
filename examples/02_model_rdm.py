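"""Build the model RDM from item features and inspect its category structure.

The RDM is 1 - Pearson correlation between item feature rows.  With positive
within-category feature correlations, items of the same category are less
dissimilar to each other than to the other category — the block structure a
CNN's hidden representations show for animate vs inanimate images.
"""

import numpy as np

from sharedrep import compute_rdm, generate_item_features, lower_triangle, rsa_score

features = generate_item_features(
    n_items=24, dim=100, within_animate_corr=0.5, within_inanimate_corr=0.3, seed=0
)
rdm = compute_rdm(features.values, features.item_ids)
n_animate = 12
within_animate = rdm.values[:n_animate, :n_animate][np.tril_indices(n_animate, -1)]
within_inanimate = rdm.values[n_animate:, n_animate:][np.tril_indices(n_animate, -1)]
between = rdm.values[n_animate:, :n_animate]

print(f"RDM shape: {rdm.values.shape}, lower triangle length {len(lower_triangle(rdm))}")
print(f"mean dissimilarity within animate:   {within_animate.mean():.3f}")
print(f"mean dissimilarity within inanimate: {within_inanimate.mean():.3f}")
print(f"mean dissimilarity between classes:  {between.mean():.3f}")
print("-> the more strongly correlated (animate) block is the tighter one;")
print("   both within-class means sit below the between-class mean.")

noisy = compute_rdm(features.values + 0.5 * np.random.default_rng(1).standard_normal(features.values.shape))
print(f"\nSpearman RSA between clean and noise-perturbed RDM: {rsa_score(rdm, noisy):.3f}")
print("   (1.0 would be identical rank geometry; chance is 0)")
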