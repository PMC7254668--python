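"""Extract the canonical 255-entry delta-radiomics vector for one lesion.

85 features per exam (21 per phase volume + 1 intra-tumor cluster entropy)
for the pre- and post-treatment exams, plus 85 deltas (af - bef).
"""

from deltarad import PhantomParams, extract_lesion_features, generate_lesion

lesion = generate_lesion(PhantomParams(seed=11), "pCR")
features = extract_lesion_features(
    lesion.pre_exam, lesion.post_exam,
    lesion.truth_mask_pre, lesion.truth_mask_post,
)

print(f"total features: {len(features)}")
for name in (
    "bef_post1_mean", "af_post1_mean", "diff_post1_mean",
    "bef_post1_entropy", "af_post1_entropy", "diff_post1_entropy",
    "bef_clusterentropy", "af_clusterentropy", "diff_clusterentropy",
):
    print(f"  {name:22s} {features[name]: .3f}")

# For this complete responder the post-treatment (af) first-post-contrast
# mean drops far below its pre-treatment (bef) value, so the delta (diff)
# mean is strongly negative - the delta-radiomics signature of response.
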