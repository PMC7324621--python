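"""Contrast energy and spatial coherence of synthetic scenes.

Renders a sparse composition, a dense texture and a pure-noise image, and
scores each with the Weibull-based contrast model.  CE (the Weibull scale)
tracks overall contrast strength; SC (the shape) moves from well below 1
for sparse, edge-dominated scenes to about 2 for dense, Gaussian-like
textures — the axis along which natural scenes differ in complexity.
"""

import numpy as np

from sceneddm import TextureParams, compute_scene_stats, generate_texture

images = {
    "sparse (10 elements)": generate_texture(
        TextureParams(n_elements=10, seed=1, shape=(128, 128))
    ),
    "dense (5000 elements)": generate_texture(
        TextureParams(n_elements=5000, seed=1, shape=(128, 128))
    ),
    "white noise": np.clip(
        0.5 + 0.1 * np.random.default_rng(0).standard_normal((128, 128)), 0, 1
    ),
}

print(f"{'image':24s} {'CE':>9s} {'SC':>6s}   {'CE(mean)':>9s} {'SC(CV)':>7s}")
for name, img in images.items():
    ml = compute_scene_stats(img, scales=(1, 2, 4), route="weibull")
    lgn = compute_scene_stats(img, scales=(1, 2, 4), route="lgn")
    print(f"{name:24s} {ml.CE:9.5f} {ml.SC:6.3f}   {lgn.CE:9.5f} {lgn.SC:7.3f}")

print(
    "\nThe sparse scene has SC well below 1 (power-law contrast histogram, a "
    "few dominant edges);\nthe dense texture and the noise image approach "
    "SC = 2 (Rayleigh/Gaussian-like contrast).\nThe moment-based columns show "
    "the fast approximation route tracking the ML Weibull fit."
)
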