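"""Build the translator-ready encodings: Mueller-channel PCA and
S0-normalized Stokes, plus the patch/stitch round trip.

The 16 Mueller element images are strongly correlated; PCA over pooled
training pixels compresses them to the top 1 or 3 channels.  The Stokes
encoding (S1/S0, S2/S0, S3/S0) needs no fitting and is invariant to
illumination intensity.
"""

import numpy as np

from polstain import apply_pca, encode_stokes, extract_patches, fit_pca, stitch_patches
from polstain.phantom import PhantomParams, generate_scene, scene_to_mueller, scene_to_stokes

scenes = [generate_scene(PhantomParams(size=(128, 128)), seed=s) for s in range(4)]
stacks = [scene_to_mueller(s) for s in scenes]

basis = fit_pca(stacks[:3], k=3)
print(f"PCA explained variance ratios: {np.round(basis.explained_ratio, 4)} "
      f"(sum {basis.explained_ratio.sum():.4f})")

enc = apply_pca(stacks[3], basis)  # held-out scene
print(f"PCA3 encoding {enc.data.shape}, range [{enc.data.min():.2f}, {enc.data.max():.2f}]")

_, stokes = scene_to_stokes(scenes[3], sop="E1")
enc_s = encode_stokes(stokes)
print(f"Stokes encoding {enc_s.data.shape}; background pixel -> "
      f"{np.round(enc_s.data[0, 0], 3)} (the illumination's own s1..s3)")

patches, layout = extract_patches(enc_s.data, size=64, stride=48)
restored = stitch_patches(patches, layout)
print(f"{len(patches)} overlapping 64 px patches; stitch error "
      f"{np.abs(restored - enc_s.data).max():.2e} (overlaps averaged)")
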