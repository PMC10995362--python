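"""Detect cones in a synthetic AO mosaic and report density/spacing/regularity.

A jittered hexagonal mosaic at 20,000 cones/mm^2 is rendered, the band-pass
detector is run on a 100 x 100 um ROI centered on the fovea, and the three
standard morphometric measures are printed next to the generator's truth.
"""

import numpy as np

from myovis import DetectionParams, ROISpec, detect_cones, mosaic_metrics
from myovis.cone_mosaic import ConeMosaic
from myovis.synthetic import MosaicSpec, gen_mosaic

spec = MosaicSpec(density=20000, jitter_sd=0.08, noise_sd=0.1, seed=1)
image, truth = gen_mosaic(spec)

roi = ROISpec(center_eccentricity=0.0, meridian="temporal", side_length=100.0)
mosaic = detect_cones(image, roi, DetectionParams(expected_spacing_um=spec.lattice_constant_um))
m = mosaic_metrics(mosaic)

off = (spec.side_um - roi.side_length) / 2
in_roi = truth[np.all((truth >= off) & (truth <= off + 100), axis=1)] - off
m_true = mosaic_metrics(ConeMosaic(positions=in_roi, roi=roi))

print(f"detected cones      : {m.n_cones}  (truth {len(in_roi)})")
print(f"density   (/mm^2)   : {m.density:8.0f}  (truth {m_true.density:8.0f})")
print(f"spacing   (um)      : {m.spacing:8.2f}  (truth {m_true.spacing:8.2f})")
print(f"regularity (%)      : {m.regularity:8.1f}  (truth {m_true.regularity:8.1f})")
print()
print("Density is cones per retinal area; spacing the mean Delaunay-neighbor")
print("distance; regularity the share of cones with 5-7 Voronoi neighbors.")
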