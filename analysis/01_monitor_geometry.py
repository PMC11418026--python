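#!/usr/bin/env python
"""Arena geometry: azimuthal coverage of the two monitor configurations.

Two 537-mm monitors meet at 120 or 65 deg with the spider 200 mm from the
junction.  This script computes the spider-centric azimuthal span each
configuration subtends, and the rear gap left when the animal faces the
junction — the three numbers that motivate running the mapping experiment
in both orientations.

Finding: the 120-deg arena spans ~197 deg, the 65-deg arena ~262 deg,
leaving ~98 deg behind the animal; presenting stimuli in both orientations
therefore tiles the full 360 deg.
"""

import argparse
from pathlib import Path

import pandas as pd

from salticid_vision.experiments import monitor_spans
from salticid_vision.geometry import MonitorSetup, angular_coverage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    spans = monitor_spans()
    rows = [
        {"configuration": "120 deg, forward",
         "coverage_deg": spans["span_120"]},
        {"configuration": "65 deg, forward",
         "coverage_deg": spans["span_65"]},
        {"configuration": "rear remainder (65 deg)",
         "coverage_deg": spans["back_remainder"]},
    ]
    # distance dependence, for the record: nearer spider -> wider span
    for d in (100.0, 200.0, 400.0):
        rows.append({
            "configuration": f"65 deg at {d:.0f} mm",
            "coverage_deg": angular_coverage(
                MonitorSetup(537.0, 65.0, d)),
        })
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "monitor_geometry.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:7.1f}"))


if __name__ == "__main__":
    main()
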