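#!/usr/bin/env python
"""Virtual experiment 1: behavioural mapping of the eye-field edges.

Virtual spiders (ALE-only or PLE-only) watch a 4-deg dot sweep one monitor
at 9 deg/s, 30 presentations per trial, one trial per arena angle (120 and
65 deg); PLE spiders additionally run both body orientations.  Traces are
scored with the first-detection criterion (first direction-consistent peak
with >= 20 deg of rotation) and detection angles are pooled into 5-deg
histograms.

Finding: detections pile up at the eye-field edges — |azimuth| ~50 deg for
ALE-only spiders (span ~100 deg), ~60 deg for forward PLE-only spiders and
~180 deg for backward ones, mapping a rear field that wraps from one ALE
edge around to the other.
"""

import argparse
from pathlib import Path

import pandas as pd

from salticid_vision.experiments import run_virtual_exp1


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-spiders", type=int, default=30)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    conditions = [
        ("ALE", "forward"),
        ("PLE", "forward"),
        ("PLE", "backward"),
    ]
    summary = []
    hist_rows = []
    for i, (treatment, orientation) in enumerate(conditions):
        res = run_virtual_exp1(treatment, orientation,
                               n_spiders=args.n_spiders,
                               seed=args.seed * 97 + i)
        h = res.histogram
        summary.append({
            "treatment": treatment,
            "orientation": orientation,
            "n_detections": res.detections.size,
            "response_rate": round(res.response_rate, 4),
            "modal_magnitude_deg": res.modal_magnitude,
            "mode_left_deg": h.mode_left,
            "mode_right_deg": h.mode_right,
            "span_deg": h.span,
        })
        for c, n, f in zip(h.centers, h.counts, h.rel_freq):
            hist_rows.append({
                "treatment": treatment, "orientation": orientation,
                "bin_center_deg": c, "count": int(n),
                "rel_freq": round(float(f), 5),
            })

    sdf = pd.DataFrame(summary)
    sdf.to_csv(args.out / "exp1_field_mapping.csv", index=False)
    pd.DataFrame(hist_rows).to_csv(
        args.out / "exp1_detection_histograms.csv", index=False)
    print(sdf.to_string(index=False))
    ale = sdf[sdf.treatment == "ALE"].iloc[0]
    print(f"\nALE span {ale.span_deg:.0f} deg -> rear complement "
          f"{360 - ale.span_deg:.0f} deg")


if __name__ == "__main__":
    main()
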