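"""Inspect the two portrait-classification architectures.

The original network takes 256 x 256 portrait images through five
AlexNet-style conv layers; the scaled-down network takes 32 x 32 images
through two conv layers.  Both end in a softmax over the enrolled
individuals.  The scale-down cuts the weight count by roughly tenfold.
"""

import ecgpsr as e

for arch, builder in [("original (256 px)", e.build_original_spec),
                      ("scaled-down (32 px)", e.build_scaled_spec)]:
    spec = builder(115)
    print(f"--- {arch}, 115 classes ---")
    print(e.describe(spec))
    print()

orig = e.count_parameters(e.build_original_spec(115))
scaled = e.count_parameters(e.build_scaled_spec(115))
print(f"weight reduction: {orig:,} -> {scaled:,} "
      f"({orig / scaled:.1f}x smaller)")
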