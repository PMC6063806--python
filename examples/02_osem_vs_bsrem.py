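"""Reconstruct one acquisition with reference OSEM and with BSREM.

Compares the clinical reference protocol (TOF OSEM, 2 iterations / 28
subsets, 5 mm + 1:4:1 post-filter) with penalized-likelihood BSREM at the
noise-matched regularization strength (beta label 400).  Expected outcome:
similar background noise, higher lesion SUVmax for BSREM — converged
penalized reconstruction recovers contrast that early-stopped, post-
filtered OSEM leaves on the table.
"""

from rdpet import (
    NoiseSpec,
    RDPParams,
    SystemModel,
    bsrem_reconstruct,
    default_geometry,
    default_pelvic_spec,
    dilate_mask,
    make_pelvic_phantom,
    osem_reconstruct,
    post_filter,
    roi_stats,
    simulate_sinogram,
    suvmax5,
)
from rdpet.calibrate import DEFAULT_BETA_SCALE

phantom = make_pelvic_phantom(default_pelvic_spec())
sino = simulate_sinogram(phantom, default_geometry(), NoiseSpec(rng_seed=0))
system = SystemModel(sino.geometry, atten=sino.atten, norm=sino.norm)

ref = osem_reconstruct(sino, system, n_iterations=2, n_subsets=28, tof=True)
ref_img = post_filter(ref.image, phantom.voxel_size_mm)

bsrem = bsrem_reconstruct(sino, system, RDPParams(beta=400 * DEFAULT_BETA_SCALE))

bkg = phantom.masks["background"]
print(f"{'':28s}{'OSEM ref':>10s}{'BSREM b400':>12s}{'true':>8s}")
r, b = roi_stats(ref_img, bkg), roi_stats(bsrem.image, bkg)
print(f"{'background SUVmean (g/ml)':28s}{r.suv_mean:10.3f}{b.suv_mean:12.3f}{1.0:8.1f}")
print(f"{'background SUVstd  (g/ml)':28s}{r.suv_std:10.3f}{b.suv_std:12.3f}{0.0:8.1f}")
for les in phantom.spec.lesions:
    m = dilate_mask(phantom.masks[les.lesion_id])
    print(f"{les.lesion_id + ' SUVmax':28s}{suvmax5(ref_img, m):10.2f}"
          f"{suvmax5(bsrem.image, m):12.2f}{les.suv:8.1f}")
# SUVstd is the noise surrogate; at the noise-matched beta BSREM should
# show equal-or-lower SUVstd with higher SUVmax in every lesion.
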