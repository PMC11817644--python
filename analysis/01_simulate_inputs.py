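"""Generate the synthetic study inputs.

Writes phantom geometry, TLD readings for the eleven measurement sessions,
a two-month-scale clinical irradiation-event log and the routine annual
workload into scratch/analysis_inputs/.  Subsequent analysis steps read
from there.  Large raw inputs stay under scratch/; only derived summary
tables go to results/.
"""

import sys
from pathlib import Path

from cathdose import pipeline

INPUT_DIR = Path("scratch/analysis_inputs")


def main(seed: int = 1) -> None:
    paths = pipeline.simulate_inputs(INPUT_DIR, seed=seed)
    print(f"Synthetic inputs written to {INPUT_DIR} (seed {seed}):")
    for name, path in paths.items():
        print(f"  {name:<10} {path}")
    print(
        "Eleven sessions simulated: nine standard projections (acquisition), "
        "one extra-large patient and one fluoroscopy variant of LAO30."
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
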