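"""Step 5 — do the two sizing routes agree?

Lines up the survey-wide cytometric diameters (mean ± sd) against the
fraction-weighted diameters and flags agreement, then checks that the
two routes rank the depths the same way for each group.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _paths import RESULTS

import picosize as ps
from picosize.compare import FCM_GROUPS


def main() -> None:
    fcm_diam = pd.read_csv(RESULTS / "fcm_diameters.csv", index_col=0)
    sm_diam = pd.read_csv(RESULTS / "sm_diameters.csv", index_col=0)["sm_um"]

    comparison = ps.compare_diameters(fcm_diam, sm_diam)
    comparison.to_csv(RESULTS / "diameter_comparison.csv")

    fcm_abund = (
        pd.read_csv(RESULTS / "fcm_summary.csv")
        .pivot(index="group", columns="depth_m", values="abundance_cells_per_ml")
    )
    vert = pd.read_csv(RESULTS / "vertical_profiles.csv", index_col=0)
    vert.columns = vert.columns.astype(float)
    concordance = pd.DataFrame(
        [ps.profile_concordance(fcm_abund.loc[g], vert.loc[g], g)
         for g in FCM_GROUPS]
    ).set_index("group")
    concordance.to_csv(RESULTS / "profile_concordance.csv")

    print("diameter agreement (FCM mean +/- sd vs SM, um):")
    for g, r in comparison.iterrows():
        flag = "within interval" if r["within_interval"] else "OUTSIDE interval"
        print(f"  {g:16s} {r['fcm_mean_um']:.2f} +/- {r['fcm_sd_um']:.2f}"
              f"  vs  {r['sm_um']:.2f}   -> {flag}")
    print("vertical-profile concordance (Spearman rho, same peak depth):")
    for g, r in concordance.iterrows():
        print(f"  {g:16s} rho = {r['spearman_rho']:+.2f}, "
              f"same argmax: {bool(r['same_argmax'])}")


if __name__ == "__main__":
    main()
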