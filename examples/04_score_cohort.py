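"""End-to-end thrombus scoring of a small synthetic two-subject study.

One subject carries a largely thrombosed false lumen, the other has no
false lumen.  After training, the latent space is partitioned automatically
(1D 2-means on the best-separating axis, thrombus side = larger vessels)
and every slice gets a thrombus score ts in [0, 1]; the subject score is
the slice mean — the quantity reported per patient dataset.
"""

import numpy as np

from flvae import (PhantomSpec, SliceLabel, VAEConfig, apply_mask_and_center,
                   dataset_score, embed_dataset, fit_partition,
                   make_phantom_cohort, thrombus_score, train)
from flvae.scoring import foreground_area, select_axis, score_track

spec = PhantomSpec()
subjects = {}
sl, _ = make_phantom_cohort(spec, {SliceLabel.THROMBOSED_FL: 50,
                                   SliceLabel.PARTIAL_FL: 30}, seed=1,
                            subject_id="dissected")
subjects["dissected"] = [apply_mask_and_center(s) for s in sl]
sl, _ = make_phantom_cohort(spec, {SliceLabel.NO_FL: 80}, seed=2,
                            subject_id="control")
subjects["control"] = [apply_mask_and_center(s) for s in sl]

images = subjects["dissected"] + subjects["control"]
params = train(images, VAEConfig(epochs=60, seed=3))

points = embed_dataset(params, images)
axis = select_axis(points)
partition = fit_partition(points, mode="auto",
                          foreground_areas=[foreground_area(im) for im in images],
                          axis=axis)
print(f"partition: axis={partition.axis} x0={partition.x0:+.3f} "
      f"xmin={partition.xmin:+.3f} ({partition.orientation})")

for sid, imgs in subjects.items():
    pts = embed_dataset(params, imgs)
    scores = [thrombus_score(p, partition, subject_id=sid) for p in pts]
    ds = dataset_score(scores)
    bins, _ = score_track(scores, colormap_bins=10)
    print(f"{sid:>10}: mean ts = {ds.mean_ts:.3f} over {ds.n_slices} slices; "
          f"track bins (first 10): {[int(b) for b in bins[:10]]}")
# The dissected subject's mean score is far above the control's, which sits
# near 0 — the same qualitative split seen between dissected patients and
# controls in clinical data.
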