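"""cogmix: cognitive-profile clustering via factor mixture models and a
conditional Gaussian-mixture variational autoencoder.

The package provides a synthetic item-response generator with the battery's
schema (54 items across six subtests plus age), an EM estimator for latent
class / factor-analysis / factor-mixture models with a binned-age covariate,
a conditional Gaussian-mixture VAE with a learnable mixture prior, the crisp
and fuzzy cluster validity index battery, and z-score cluster profiling.
"""

from . import cgmvae, cluster_quality, fmm, pipeline, profiling, schema, synthetic

__all__ = [
    "schema",
    "synthetic",
    "fmm",
    "cgmvae",
    "cluster_quality",
    "profiling",
    "pipeline",
]

__version__ = "0.1.0"
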