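"""Run both forward models on one stimulus object.

Builds the object with list-of-parts code 0000, renders the three
orthographic depth views and simulates the 24-grasp exploration,
printing the dimensionality contracts and a few summary statistics.
"""

import numpy as np

from mvh import GraspConfig, RenderConfig, forward, haptic_features, render_views
from mvh.stimuli import make_object

rep = make_object("0000")

visual = render_views(rep, RenderConfig(resolution=200))
print(f"visual vector: {len(visual)} features (3 views x 200 x 200 pixels)")
print(f"  occupied pixels: {np.count_nonzero(visual.vector)} "
      f"({100 * np.count_nonzero(visual.vector) / len(visual):.1f}% of the window)")

haptic = haptic_features(rep, GraspConfig())
print(f"haptic vector: {len(haptic)} features (16 pseudo joint angles x 24 grasps)")
print(f"  contact rays: {np.count_nonzero(haptic.vector < np.pi / 2)} of 384 "
      f"(a finger that never touches the object closes fully to pi/2)")

both = forward(rep, ("visual", "haptic"), RenderConfig(resolution=200))
print(f"multisensory vector: {len(both)} features "
      f"(each modality block scaled by 1/sqrt(dim) before concatenation)")
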