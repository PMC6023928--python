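#!/usr/bin/env python
"""Measure canalicular morphometry in a 20-eye healthy phantom cohort.

Each eye's anatomy is drawn from the healthy-cohort distributions
(vertical AP 356 ± 82 µm, horizontal AP 143 ± 23 µm, transverse
2900 ± 421 µm, epithelium 89 ± 12 µm), imaged at the contrast peak,
segmented, traced and measured at three 1-mm stations. Writes the per-eye
table and a cohort summary under results/.
"""

from pathlib import Path

from octd.study import morphometry_cohort

ROOT = Path(__file__).resolve().parents[1]
N_EYES = 20
SEED = 1


def main() -> None:
    df = morphometry_cohort(N_EYES, SEED)
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    df.to_csv(res / "cohort_morphometry.csv", index=False)

    cols = [
        ("vertical_ap_um", "true_vertical_ap_um"),
        ("horizontal_ap_um", "true_horizontal_ap_um"),
        ("transverse_um", "true_transverse_um"),
        ("lumen_area_mm2", "true_lumen_area_mm2"),
        ("epithelium_um", "true_epithelium_um"),
    ]
    print(f"{N_EYES}-eye healthy cohort (measured vs generated truth):")
    for meas, truth in cols:
        print(
            f"  {meas:20s} {df[meas].mean():9.3f} ± {df[meas].std(ddof=1):7.3f}"
            f"   truth {df[truth].mean():9.3f} ± {df[truth].std(ddof=1):7.3f}"
        )
    print(f"  mean segmentation Dice vs ground truth: {df.dice.mean():.3f}")


if __name__ == "__main__":
    main()
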