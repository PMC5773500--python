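#!/usr/bin/env python
"""3D particle segmentation on a synthetic sphere field with a nucleus.

Places non-overlapping fluorescent spheres with volumes shrinking away
from an ellipsoidal nucleus (the perinuclear-accumulation geometry),
segments them with the distance-transform-seeded watershed, measures
per-object volume / intensity / centroid and signed distance to the
nucleus surface, and bins the objects in 0.5 µm distance shells.
Outputs under results/seg3d/.
"""

from pathlib import Path

import numpy as np
import tifffile

from carpetfcs import seg3d
from carpetfcs.carpet_io import write_results_table
from carpetfcs.protocols import sphere_recovery
from carpetfcs.simcarpet import simulate_sphere_field

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "seg3d"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    iso = (55.0, 55.0, 55.0)
    nuc = {"center_vox": (16, 40, 16), "semiaxes_vox": (12, 30, 12)}
    radii = [5.0, 5.0, 4.0, 4.0, 3.0, 3.0]
    centers = [(16, 32, 36), (16, 48, 36), (16, 32, 46),
               (16, 48, 46), (16, 32, 56), (16, 48, 56)]
    field = simulate_sphere_field(6, radii, intensity=80.0, shape=(32, 80, 96),
                                  voxel_size_nm=iso, centers_vox=centers,
                                  nucleus_mask_spec=nuc)
    labels, objects = seg3d.segment_particles(field.stack, intensity_threshold=40.0)
    objects = seg3d.distance_to_nucleus(objects, field.nucleus_mask, iso)
    tifffile.imwrite(OUT / "labels.tif", labels.astype(np.int32))
    write_results_table(seg3d.objects_to_frame(objects), OUT / "objects.csv")
    write_results_table(field.truth, OUT / "truth.csv")
    bins = seg3d.bin_by_distance(objects, bin_width_um=0.5)
    write_results_table(bins, OUT / "distance_bins.csv")

    print(f"segmented {len(objects)}/{len(field.truth)} planted spheres")
    for _, row in bins[bins["n_objects"] > 0].iterrows():
        print(f"  {row['bin_left_um']:.1f}-{row['bin_right_um']:.1f} µm: "
              f"n={row['n_objects']:.0f}  volume {row['mean_volume_um3']:.3f} µm³")
    rec = sphere_recovery(seed=1)
    print(f"random-field check: {rec['n_found']}/{rec['n_planted']} objects, "
          f"max volume error {100 * rec['max_volume_error']:.1f}%, "
          f"touching pair split into {rec['touching_pair_objects']}")


if __name__ == "__main__":
    main()
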