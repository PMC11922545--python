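"""Generate a ground-truthed synthetic tumor section and save its images.

Builds a 512 x 512 px (584 um) section with two implanted subpopulations —
a hypoxic focus (pimo+/HIF+, depressed redox ratio) and a "ROS" focus
(pimo-/HIF+, elevated redox ratio) — plus Poisson photon noise and a known
misregistration of the IHC modality.
"""

from pathlib import Path

import redoxmap as rm
from redoxmap.io import save_landmarks, save_section_image

out = Path("scratch/example_section")
out.mkdir(parents=True, exist_ok=True)

config = rm.GeneratorConfig(seed=42)
section = rm.generate_section(config)
truth = section.truth

tissue = truth.mask_true
print(f"section shape: {config.shape}, pixel size {config.pixel_size:.4f} um/px")
print(f"tissue pixels: {tissue.sum()} ({tissue.mean() * 100:.1f}% of frame)")
for i, sub in enumerate(config.subpop_spec, start=1):
    frac = (truth.region_label == i)[tissue].mean()
    print(f"  subpop {sub.name!r}: {frac * 100:.2f}% of tissue "
          f"(pimo={sub.pimo}, hif={sub.hif}, ORR {sub.mean_orr})")
print(f"true pimo+ fraction: {truth.pimo_field[tissue].mean() * 100:.2f}%  "
      f"true HIF+ fraction: {truth.hif_field[tissue].mean() * 100:.2f}%")

# misregister the IHC channels as staining + re-mounting would
moved, (pair_fixed, pair_moving) = rm.misregister(
    list(section.ihc_images), truth.transform_true, truth.landmarks
)
for name, img in [("nadh", section.nadh), ("fad", section.fad)]:
    save_section_image(img, out / f"{name}.tif")
for name, img in zip(("ihc_red_755", "ihc_red_950", "ihc_green_950"), moved):
    save_section_image(img, out / f"{name}.tif")
save_landmarks(pair_fixed, pair_moving, out / "landmarks.csv")
print(f"wrote TIFFs and landmark CSV to {out}/")
print("the landmark pairs encode the true (unknown to the pipeline) "
      f"misregistration: scale {config.misreg_scale}, "
      f"rotation {config.misreg_rotation_deg} deg, "
      f"translation {config.misreg_translation} px")
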