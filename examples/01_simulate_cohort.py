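"""Simulate a small phantom cohort and look at its enhancement kinetics.

Each lesion is a paired pre-/post-chemotherapy exam of four phase volumes
(pre-contrast + three post-contrast).  Complete responders (pCR) shrink
and lose enhancement after treatment; non-responders do not.
"""

import numpy as np

from deltarad import PhantomParams, generate_cohort

params = PhantomParams(seed=7)
lesions, clinical = generate_cohort(n_lesions=8, pcr_fraction=0.5, params=params)

print(clinical)
print()
for lesion in lesions[:4]:
    pre_mask = lesion.truth_mask_pre.mask
    post_mask = lesion.truth_mask_post.mask
    pre_curve = [lesion.pre_exam.phases[k][pre_mask].mean() for k in range(4)]
    post_curve = [lesion.post_exam.phases[k][post_mask].mean() for k in range(4)]
    print(
        f"{lesion.lesion_id} ({lesion.label:6s}) "
        f"pre-NAC lesion means {np.round(pre_curve, 1)} | "
        f"post-NAC {np.round(post_curve, 1)}"
    )

# The pre-NAC curves rise steeply after contrast (multipliers ~2.2-2.6 over
# baseline).  For pCR lesions the post-NAC curve is nearly flat: the
# residual tumor bed barely enhances.  That contrast is the signal the
# classifier learns.
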