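"""Compare the three object-similarity back-ends against ratings.

Builds the 16 stimuli, computes the modality-independent (tree edit
distance), visual and haptic similarity matrices, generates a synthetic
rating table driven by the list-of-parts code, and prints the Pearson
correlation of each model metric with the ratings.
"""

from mvh import (
    RenderConfig,
    condition_matrix,
    mvh_h_similarity,
    mvh_m_similarity,
    mvh_v_similarity,
    pearson_r,
    subject_matrices,
)
from mvh.stimuli import all_objects, synth_ratings

stimuli = all_objects()
ratings_df = synth_ratings(noise_sd=0.0, n_subjects=7, n_blocks=4, seed=0)
ratings = condition_matrix(subject_matrices(ratings_df)["visual"])

labels = ratings.labels
matrices = {
    "MVH-M": mvh_m_similarity(stimuli, labels=labels),
    "MVH-V": mvh_v_similarity(stimuli, RenderConfig(resolution=64), labels=labels),
    "MVH-H": mvh_h_similarity(stimuli, labels=labels),
}

print("correlation with code-driven ratings (136 object pairs):")
for name, matrix in matrices.items():
    print(f"  {name}: R = {pearson_r(matrix, ratings):.4f}")
print("\nThe modality-independent metric tracks the ratings best because "
      "both are functions of how many parts two objects share; the "
      "sensory-space metrics blur that structure through rendering and "
      "grasping geometry.")
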