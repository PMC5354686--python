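"""Generate a synthetic bilateral-breast DCE-MRI phantom and inspect its truth.

The phantom has known whole-breast, FGT and enhanced-FGT masks, so the true
BPER (enhanced FGT / total FGT x 100) per breast and phase is exact.
"""

import bpeq

spec = bpeq.PhantomSpec(shape=(96, 96, 32), sigma_noise=5.0, seed=0)
pre, posts, truth = bpeq.generate_phantom(spec)

print(f"grid {spec.shape}, spacing {spec.spacing} mm, noise sigma {spec.sigma_noise}")
for side in ("left", "right"):
    n_breast = truth.breast[side].sum()
    n_fgt = truth.fgt[side].sum()
    print(f"{side:>5} breast: {n_breast} voxels, FGT {n_fgt} ({100*n_fgt/n_breast:.0f}%)")
for phase in bpeq.PHASES:
    vals = truth.true_bper[phase]
    print(f"true BPER at {phase} ({bpeq.PHASE_MINUTES[phase]:.0f} min): "
          f"left {vals['left']:.2f}%  right {vals['right']:.2f}%")
# Later phases enhance a larger share of FGT, so true BPER rises with time,
# as background parenchymal enhancement does in vivo.
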