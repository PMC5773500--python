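#!/usr/bin/env python
"""Number & brightness analysis of the reference carpet.

Runs both segmentation schemes on the capsid channel (fast: 300-line
segments; slow: 100-line averages over the whole record), joins them to
the per-column speed classes, builds the brightness-vs-distance
histogram around the lamina, and scans the nucleoplasmic intensity trace
for rare bright transits.  Tables land under results/numbright/.
"""

from pathlib import Path

import numpy as np

from carpetfcs import corrspec, fcsfit, numbright, zones
from carpetfcs.carpet_io import read_carpet, write_results_table

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim" / "carpet.tif"
OUT = ROOT / "results" / "numbright"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    carpet = read_carpet(SIM)
    nb_fast = numbright.nb_compute(
        carpet, numbright.NBSegmentationScheme("fast", block_lines=300), channel=1)
    nb_slow = numbright.nb_compute(
        carpet, numbright.NBSegmentationScheme("slow", average_window=100), channel=1)
    write_results_table(nb_fast, OUT / "nb_fast.csv")
    write_results_table(nb_slow, OUT / "nb_slow.csv")
    print(f"fast scheme: mean B {nb_fast['B_apparent'].mean():.2f} over "
          f"{nb_fast['segment_id'].nunique()} segments")
    print(f"slow scheme: mean B {nb_slow['B_apparent'].mean():.2f} "
          "(100-line averages expose the slow bright aggregates)")

    fits = fcsfit.fit_carpet(corrspec.acf_carpet(carpet, channel=1))
    joint = numbright.joint_speed_partition(nb_fast, nb_slow, fits)
    write_results_table(joint, OUT / "nb_joint.csv")
    for cls, grp in joint.groupby("speed_class"):
        print(f"  {cls}: n={len(grp)}  N = {grp['N'].mean():.2f}  "
              f"B = {grp['B'].mean():.2f}")

    lamina = zones.detect_lamina(carpet, 0)
    zone_map = zones.assign_zones(lamina, 11,
                                  zones.infer_orientation(carpet, lamina, 1),
                                  carpet.n_pixels)
    hist = numbright.brightness_vs_distance(nb_slow, zone_map,
                                            carpet.pixel_size_nm,
                                            bin_width_um=0.25)
    write_results_table(hist, OUT / "brightness_vs_distance.csv")
    peak = hist.loc[hist["mean_B"].idxmax()]
    print(f"slow-scheme brightness peaks {abs(peak['bin_center_um']):.2f} µm on the "
          f"{'cytoplasmic' if peak['bin_center_um'] < 0 else 'nucleoplasmic'} side "
          "of the lamina (planted aggregates at 1.0 µm)")

    # rare-transit scan on a nucleoplasmic column
    nucleo_cols = np.nonzero(zone_map.labels == "nucleoplasm")[0]
    col = int(nucleo_cols[len(nucleo_cols) // 2])
    series = carpet.data[:, col, 1].astype(float)
    smooth = np.convolve(series, np.ones(50) / 50, mode="same")
    peaks = numbright.detect_rare_peaks(smooth, min_prominence=5 * smooth.std(),
                                        min_separation=500)
    write_results_table(peaks, OUT / "rare_peaks.csv")
    print(f"rare bright transits in nucleoplasmic column {col}: {len(peaks)}")


if __name__ == "__main__":
    main()
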