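#!/usr/bin/env python
"""Build the synthetic shelf: survey samples, altimetry grid, north wall.

Writes the station table, north-wall series and ground truth under
scratch/data/ (they are bulky and fully regenerable); later steps read
from there.
"""

from pathlib import Path

from copetrend import synthetic

SEED = 1
OUT = Path("scratch/data")


def main() -> None:
    truth = synthetic.default_truth(seed=SEED)
    paths = synthetic.write_outputs(truth, OUT)
    samples = synthetic.generate_abundance(truth)
    n_cruises = samples["cruise_id"].nunique()
    print(f"world seed={SEED}, years {truth.years[0]}-{truth.years[1]}")
    print(f"  {len(samples)} sample rows from {n_cruises} cruises "
          f"({truth.stations_per_bin} stations/bin)")
    print(f"  southern gap: {truth.gap_spec}")
    print(f"  mean alongshore flow {truth.mean_alongshore} cm/s, "
          f"GSNWI coupling {truth.coupling_gsnwi_velocity}")
    for k, p in paths.items():
        print(f"  wrote {p}")


if __name__ == "__main__":
    main()
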