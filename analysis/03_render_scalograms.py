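#!/usr/bin/env python
"""Render example scalogram images for one NTS and one HTS subject.

Converts a handful of 10-s PPG sub-segments to Morse-(3,60) CWT scalograms
(12 voices per octave), rendered as 224 x 224 RGB images with the cone of
influence overdrawn in white, and writes the PNGs plus an image manifest.
"""

import argparse
from pathlib import Path

import pandas as pd

from ppgcal import (
    generate_cohort, preprocess_cohort, render_segments,
    separable_cohort_config, write_images,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-per-class", type=int, default=3)
    args = ap.parse_args()
    img_dir = args.out / "example_scalograms"

    cohort = generate_cohort(separable_cohort_config(args.seed, n_per_class=1,
                                                     recordings_per_subject=1))
    pre = preprocess_cohort(cohort)
    by_label: dict[str, list] = {"NTS": [], "HTS": []}
    for seg in pre.segments:
        if len(by_label[seg.label]) < args.n_per_class:
            by_label[seg.label].append(seg)
    chosen = by_label["NTS"] + by_label["HTS"]

    images = render_segments(chosen)
    write_images(images, img_dir)
    rows = [{"image_path": f"example_scalograms/{s.segment_id}.png",
             "subject_id": s.subject_id, "recording_id": s.recording_id,
             "parity_index": s.parity_index, "t0": s.t0, "label": s.label}
            for s in chosen]
    pd.DataFrame(rows).to_csv(args.out / "image_manifest.csv", index=False)
    print(f"rendered {len(images)} scalograms "
          f"({args.n_per_class} per class) to {img_dir}")
    print("each image is 224 x 224 x 3; white trace marks the cone of "
          "influence")


if __name__ == "__main__":
    main()
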