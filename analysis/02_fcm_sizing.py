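"""Step 2 — flow-cytometry route.

Gates each depth's event table into Prochlorococcus / Synechococcus /
picoeukaryotes, tabulates abundances and per-depth diameters, and pools
all events into the survey-wide mean ± sd diameter per population.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _paths import CALIBRATION, EVENTS_DIR, RESULTS, VOLUME_ML

from picosize import fcm, io


def main() -> None:
    rows, pooled = [], []
    for path in sorted(EVENTS_DIR.glob("events_*.tsv")):
        labeled = fcm.gate_populations(io.read_event_table(path))
        depth = float(path.stem.split("_")[1].rstrip("m"))
        summary = fcm.population_summary(labeled, VOLUME_ML, cal=CALIBRATION)
        summary["depth_m"] = depth
        rows.append(summary.reset_index())
        pooled.append(labeled)

    table = pd.concat(rows, ignore_index=True)
    table.to_csv(RESULTS / "fcm_summary.csv", index=False)
    diam = fcm.pooled_diameter_table(pd.concat(pooled, ignore_index=True),
                                     cal=CALIBRATION)
    diam.to_csv(RESULTS / "fcm_diameters.csv")

    print("survey-wide FCM diameters (um):")
    for g, r in diam.iterrows():
        print(f"  {g:16s} {r['mean']:.2f} +/- {r['sd']:.2f}")


if __name__ == "__main__":
    main()
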