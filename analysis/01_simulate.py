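"""Step 1 — simulate the survey.

Generates the ground-truthed synthetic station: environmental profiles,
the size-fractionated OTU/taxonomy tables (16S + 18S, six depths, three
fractions) and per-depth flow-cytometry event tables.  Summary inputs go
to ``results/``; the event tables are bulky and go to ``scratch/``.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _paths import (
    CALIBRATION,
    EVENTS_DIR,
    N_CELLS,
    N_EVENTS_PEAK,
    READ_DEPTH,
    RESULTS,
    SEED,
    VOLUME_ML,
)

import picosize as ps
from picosize import io


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    EVENTS_DIR.mkdir(parents=True, exist_ok=True)

    truth = ps.with_contaminants(ps.default_community(seed=SEED))
    env = ps.simulate_environment(truth.depths, seed=SEED)
    otu, tax, _ = ps.simulate_dataset(
        truth, n_cells=N_CELLS, read_depth=READ_DEPTH, seed=SEED
    )
    events = ps.simulate_event_series(
        truth, N_EVENTS_PEAK, analyzed_volume_ml=VOLUME_ML, cal=CALIBRATION,
        seed=SEED
    )

    io.write_env_profile(env, RESULTS / "environment.csv")
    io.write_otu_table(otu, RESULTS / "otu_raw.tsv")
    io.write_taxonomy(tax, RESULTS / "taxonomy.tsv")
    for depth, ev in events.items():
        io.write_event_table(ev, EVENTS_DIR / f"events_{depth:g}m.tsv")

    print(f"simulated {otu.shape[0]} OTUs x {otu.shape[1]} samples "
          f"and {sum(len(e) for e in events.values())} FCM events "
          f"over {len(truth.depths)} depths (seed {SEED})")


if __name__ == "__main__":
    main()
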