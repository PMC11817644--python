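"""Clinical exposure distribution: filter and bin the irradiation events.

Keeps events within ±45° rotation and angulation, bins them on the 3x3
projection grid per modality, and normalizes each cell's P_KA by the
in-range total.  Writes results/bin_fractions.csv and prints the retention
and modality split.
"""

import io
from pathlib import Path

import pandas as pd

from cathdose import binning, pipeline

INPUT_DIR = Path("scratch/analysis_inputs")
RESULTS = Path("results")


def main() -> None:
    events = pd.read_csv(INPUT_DIR / pipeline.EVENTS_FILE)
    result, table, _ = pipeline.run_binning(events)
    fractions = binning.bin_fractions(table)
    RESULTS.mkdir(exist_ok=True)
    binning.bin_table_to_csv(table, fractions, RESULTS / "bin_fractions.csv")
    fluoro_share = table.modality_pka("fluoroscopy") / table.in_range_pka
    print(
        f"Retained {result.n_retained}/{result.n_total} events "
        f"({100 * result.retained_fraction:.1f}%) within ±45° on both axes."
    )
    print(
        f"In-range P_KA {table.in_range_pka:.1f} Gy cm2, of which "
        f"{100 * fluoro_share:.1f}% from fluoroscopy."
    )
    print(f"Per-cell fractions -> {RESULTS / 'bin_fractions.csv'}")


if __name__ == "__main__":
    main()
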