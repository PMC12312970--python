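"""Peripheral vs central chromatin-marker localization.

Builds a spherical nucleus with two synthetic marker channels — one
concentrated near the nuclear envelope (heterochromatin-like, H3K9Me3)
and one concentrated centrally (euchromatin-like, H3K9Ac) — and
quantifies each with a radial profile and the peripheral-enrichment
index (PEI: > 1 means envelope-proximal enrichment).
"""

import numpy as np
from scipy import ndimage

from nucleomorph import (
    VoxelGrid,
    generate_nucleus,
    peripheral_enrichment,
    radial_profile,
)
from nucleomorph.phantom import NucleusSpec, PhantomSpec

spec = PhantomSpec(
    shape=(56, 64, 64),
    nuclei=(NucleusSpec((2.8, 2.8, 2.8), (28, 32, 32)),),
    texture_amplitude=0.0, gaussian_noise_sd=0.0,
    psf_sigma_nm=(0, 0, 0), background=0.0, seed=0,
)
grid, labels, _ = generate_nucleus(spec)
region = labels.labels == 1

edt = ndimage.distance_transform_edt(region, sampling=np.asarray(grid.spacing))
depth = np.where(region, edt / edt.max(), 0.0)  # 0 = envelope, 1 = centre

peripheral_marker = VoxelGrid(
    np.where(region, np.exp(-depth / 0.15), 0.0), grid.spacing, "H3K9Me3"
)
central_marker = VoxelGrid(
    np.where(region, np.exp(-(1 - depth) / 0.3), 0.0), grid.spacing, "H3K9Ac"
)

for marker in (peripheral_marker, central_marker):
    profile = radial_profile(marker, region, n_bins=10)
    pei = peripheral_enrichment(profile, shell_fraction=0.2)
    bins = ", ".join(f"{v:.2f}" for v in profile.mean_intensity)
    print(f"{marker.channel_name:>8}: bin means (envelope->centre) [{bins}]")
    print(f"{'':>8}  peripheral-enrichment index = {pei:.2f}")

# The envelope-associated marker yields PEI >> 1, the central marker
# PEI << 1; a uniformly distributed marker would give PEI = 1.
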