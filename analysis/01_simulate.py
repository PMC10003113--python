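"""Generate one example synthetic dataset of every kind and save it.

Writes TIFF images with JSON truth sidecars and CSV time series under
``results/synthetic/`` so the later analysis steps (and a curious reader)
have concrete files to look at.  Every downstream script regenerates its own
inputs from seeds, so this step is illustrative, not a dependency.
"""

import argparse
from pathlib import Path

from photoskin.images import write_image, write_truth_sidecar
from photoskin.synth import (
    gen_conversion_curve,
    gen_melatonin_series,
    gen_micropattern_image,
    gen_mito_image,
    gen_stain_image,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    for label, frag in (("untreated", 0.1), ("blue_light", 0.8)):
        image, truth = gen_mito_image(fragmentation=frag, seed=args.seed)
        write_image(out / f"mito_{label}.tif", image)
        write_truth_sidecar(
            out / f"mito_{label}.truth.json",
            {"fragmentation": truth.fragmentation, "n_trees": truth.n_trees,
             "total_length_um": truth.total_length, "seed": truth.seed},
        )
        print(f"mito {label}: {truth.n_trees} trees, {truth.total_length:.0f} um total length")

    image, truth = gen_micropattern_image(n_cells=30, seed=args.seed)
    write_image(out / "micropattern.tif", image)
    write_truth_sidecar(
        out / "micropattern.truth.json",
        {"areas_um2": truth.areas, "pitch_um": truth.pitch, "seed": truth.seed},
    )
    print(f"micropattern: 30 cells, mean true area {truth.areas.mean():.0f} um^2")

    image, truth = gen_stain_image(f=0.3, seed=args.seed)
    write_image(out / "stain_section.tif", image)
    write_truth_sidecar(
        out / "stain_section.truth.json",
        {"stained_fraction": truth.stained_fraction, "hue_band": truth.hue_band, "seed": truth.seed},
    )
    print(f"stain section: stained fraction {truth.stained_fraction:.3f} in ROI")

    series, truth = gen_melatonin_series(
        suppression={"untreated": 0.0, "blue light": 0.9, "blue light + extract": 0.2},
        seed=args.seed,
    )
    series.to_csv(out / "melatonin_series.csv", index=False)
    print(f"melatonin series: {len(series)} samples, conditions {sorted(truth.suppression)}")

    table, truth = gen_conversion_curve(seed=args.seed, noise_cv=0.05)
    table.to_csv(out / "crocin_conversion.csv", index=False)
    print(f"conversion curve: {len(table)} time points, c0 = {truth.c0_mM} mM")


if __name__ == "__main__":
    main()
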