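"""Generate a labeled synthetic powder-image campaign.

Builds 90 images of black pepper adulterated with sea foam (meerschaum) at
0, 5, 15, 30 and 50% mass fraction and prints the per-level mean gray
value: brightening with the adulterant fraction is the physical signal the
detection pipeline exploits.
"""

import numpy as np

import spicevision as sv

cfg = sv.SimConfig(images_per_level=18, image_size=(128, 128), seed=0)
dataset = sv.generate_dataset(sv.BLACK_PEPPER, sv.SEA_FOAM, cfg)
print(f"generated {len(dataset)} images, "
      f"{cfg.images_per_level} per level, levels {cfg.levels}")

for class_index, w in enumerate(cfg.levels, start=1):
    imgs = [im for im, lab in zip(dataset.images, dataset.labels)
            if lab == class_index]
    gray = np.mean([0.2989 * im[..., 0].mean() + 0.5870 * im[..., 1].mean()
                    + 0.1140 * im[..., 2].mean() for im in imgs])
    print(f"  level {w:4.0%}: mean gray {gray:.3f}")

# mean gray rises with w because the mineral adulterant is lighter than
# the pepper; pure black pepper sits near 0.47.
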