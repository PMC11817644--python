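"""Exposure-weighted conversion coefficients.

Scales the single fluoroscopy measurement's CC ratio onto every projection,
then weights all 18 (projection, modality) cells by their clinical P_KA
fractions into one CC per target.  Writes results/weighted_ccs.csv.
"""

from pathlib import Path

import pandas as pd

from cathdose import pipeline

INPUT_DIR = Path("scratch/analysis_inputs")
RESULTS = Path("results")


def main() -> None:
    cc_table = pd.read_csv(RESULTS / "cc_table.csv", index_col="configuration")
    bins = pd.read_csv(RESULTS / "bin_fractions.csv")
    fractions = {
        (row["projection"], row["modality"]): row["fraction"]
        for _, row in bins.iterrows()
    }
    cc_set, weighted = pipeline.run_weighting(cc_table, fractions)
    out = pd.Series(weighted, name="weighted_cc_ugy_per_gycm2")
    out.to_csv(RESULTS / "weighted_ccs.csv")
    print("Weighted CCs (µGy per Gy cm2):")
    print(out.round(2).to_string())
    ratio_b = weighted["left"] / weighted["right"]
    ratio_e = weighted["left_eye"] / weighted["right_eye"]
    print(f"\nWeighted left/right ratios: brain x{ratio_b:.1f}, eye x{ratio_e:.1f}.")


if __name__ == "__main__":
    main()
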