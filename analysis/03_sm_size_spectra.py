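"""Step 3 — size-fractionation route.

Filters the OTU table (abundance, annotation confidence, non-target
lineages), computes each group's read distribution over the 0.2-0.6 /
0.6-1.2 / 1.2-2 um fractions, the midpoint-weighted diameters, and the
vertical read profiles.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _paths import RESULTS

import picosize as ps
from picosize import io
from picosize.compare import FCM_GROUPS


def main() -> None:
    otu = io.read_otu_table(RESULTS / "otu_raw.tsv")
    tax = io.read_taxonomy(RESULTS / "taxonomy.tsv")

    filtered, flog = ps.filter_otus(otu, tax)
    io.write_otu_table(filtered, RESULTS / "otu_filtered.tsv")
    (RESULTS / "filter_log.json").write_text(json.dumps(
        {k: sorted(getattr(flog, k)) for k in
         ("low_abundance", "low_confidence", "excluded_lineage", "unannotated")},
        indent=2))

    profiles, diams = {}, {}
    for g in FCM_GROUPS:
        prof = ps.fraction_proportions(filtered, tax, g, normalize="raw")
        profiles[g] = prof
        diams[g] = ps.estimate_diameter_sm(prof)
    pd.DataFrame(profiles).T.to_csv(RESULTS / "fraction_proportions.csv")
    diam = pd.Series(diams, name="sm_um")
    diam.to_frame().to_csv(RESULTS / "sm_diameters.csv")

    vert = ps.vertical_profiles(filtered, tax, FCM_GROUPS, normalize="raw")
    vert.to_csv(RESULTS / "vertical_profiles.csv")

    print(f"kept {filtered.shape[0]}/{otu.shape[0]} OTUs")
    print("fraction-weighted SM diameters (um):")
    for g, d in diam.items():
        pcts = " / ".join(f"{100 * p:.1f}%" for p in profiles[g])
        print(f"  {g:16s} {d:.2f}   ({pcts})")


if __name__ == "__main__":
    main()
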