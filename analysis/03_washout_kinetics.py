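#!/usr/bin/env python
"""Washout half-life (T1/2) in a 20-eye phantom cohort.

Per eye, ROI time-intensity curves are read in the vertical and horizontal
segments from the background-subtracted series, and T1/2 is the time from
the intensity maximum to the first sample strictly below half of it. True
half-lives are drawn around 6.1 min, so on the one-minute sampling grid the
estimator should read ~0.5 min above truth on average.
"""

from pathlib import Path

from octd.study import kinetics_cohort

ROOT = Path(__file__).resolve().parents[1]
N_EYES = 20
SEED = 2


def main() -> None:
    df = kinetics_cohort(N_EYES, SEED)
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    df.to_csv(res / "cohort_kinetics.csv", index=False)

    print(f"{N_EYES}-eye washout cohort:")
    print(
        f"  T1/2 vertical   {df.t_half_vertical_min.mean():.2f} ± "
        f"{df.t_half_vertical_min.std(ddof=1):.2f} min "
        f"({int(df.censored_vertical.sum())} censored)"
    )
    print(
        f"  T1/2 horizontal {df.t_half_horizontal_min.mean():.2f} ± "
        f"{df.t_half_horizontal_min.std(ddof=1):.2f} min "
        f"({int(df.censored_horizontal.sum())} censored)"
    )
    print(
        f"  true half-life  {df.true_half_life_min.mean():.2f} ± "
        f"{df.true_half_life_min.std(ddof=1):.2f} min; grid-quantized "
        f"expectation {df.expected_grid_t_half_min.mean():.2f} min"
    )


if __name__ == "__main__":
    main()
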