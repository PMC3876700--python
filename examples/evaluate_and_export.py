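"""Write a phantom to disk, segment it from the file, and evaluate.

Shows the on-disk workflow: images and masks are ordinary PNG rasters,
so results interoperate with any other tool.  Masks are written with
vessel=255 and read back as {0,1} arrays.
"""

import tempfile
from pathlib import Path

import imageio.v3 as iio

import retivess as rv

workdir = Path(tempfile.mkdtemp())
img, gold = rv.generate_phantom(
    rv.PhantomSpec(shape=(256, 256), n_vessels=4, width_range=(2.0, 16.0), seed=17)
)
iio.imwrite(workdir / "phantom.png", img.pixels)
rv.write_mask(gold, workdir / "gold.png")

fundus = rv.read_fundus(workdir / "phantom.png")
cfg = rv.SegmentationConfig()
cfg.pyramid.max_vessel_width = 16
mask = rv.segment(fundus, cfg)
rv.write_mask(mask, workdir / "pred.png")

r = rv.evaluate(rv.read_mask(workdir / "pred.png"), rv.read_mask(workdir / "gold.png"))
print(f"files in {workdir}")
print(f"TP={r.tp} FP={r.fp} FN={r.fn} TN={r.tn}")
print(f"Se={r.sensitivity:.4f} Sp={r.specificity:.4f} Acc={r.accuracy:.4f}")
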