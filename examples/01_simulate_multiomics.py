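"""Generate a synthetic three-modality staging cohort and inspect it.

Builds methylation-like (bounded [0,1]), RNA-seq-like (continuous log scale)
and CNV-like (integer calls in [-2,2]) tables sharing one ordered class
signal, then prints their shapes, value ranges and the class balance.
"""

import numpy as np

from omicforest import SimSpec, generate

res = generate(
    SimSpec(
        n_per_class=(31, 49, 8),  # 1/5-scale stage I/II/III imbalance
        dims=(340, 320, 39),
        n_informative=(25, 25, 8),
        effect_size=1.5,
        seed=42,
    )
)

print("class counts:", np.bincount(res.labels.labels).tolist(), res.labels.class_names)
for modality, fm in res.feature_matrices.items():
    v = fm.values
    print(
        f"{modality:12s} {v.shape[0]:3d} x {v.shape[1]:3d}  "
        f"range [{v.min():6.2f}, {v.max():6.2f}]  "
        f"informative features: {len(res.informative[modality])}"
    )

# The latent factor orders the classes: its class means sit ~1 unit apart.
for c in range(3):
    z_c = res.latent[res.labels.labels == c]
    print(f"latent stage factor, class {c}: mean {z_c.mean():.2f} sd {z_c.std():.2f}")
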