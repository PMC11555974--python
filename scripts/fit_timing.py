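"""Regenerate the packaged time-location coefficients for the lifetime method.

Runs microsimulations in which mortality drifts linearly over the final
decades, reads off the time at which the period survivorship equalled each
age group's lifetime estimate, and fits T(n) = c0(n) + c1(n) * ln(5S) per
respondent age group, writing the result to
src/sibsurv/data/timing_coefficients.csv.

Usage: python scripts/fit_timing.py [--seed 0] [--out <path>]
"""

import argparse
from pathlib import Path

from sibsurv.experiments import design_grid, fit_timing_coefficients

HEADER = """\
# Time location of lifetime-method estimates: years before the survey
# T(n) = c0 + c1*ln(5S), fitted across the package's stable-population
# simulation grid (regenerate with scripts/fit_timing.py).
"""


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument(
        "--out",
        default=Path(__file__).resolve().parents[1]
        / "src" / "sibsurv" / "data" / "timing_coefficients.csv",
    )
    args = ap.parse_args()
    configs = design_grid(target_final_size=12_000, base_seed=args.seed)[::8]
    table = fit_timing_coefficients(base_configs=configs)
    out = Path(args.out)
    out.write_text(HEADER + table.to_csv(index=False))
    print(table.to_string(index=False))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
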