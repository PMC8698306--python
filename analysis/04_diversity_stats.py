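"""Step 4 — diversity and environmental statistics.

Alpha-diversity indices per sample, tests for differences across size
fractions, and Pearson correlations of each group's vertical profile
(both routes) with the environmental factors.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _paths import RESULTS

from picosize import io, stats


def main() -> None:
    filtered = io.read_otu_table(RESULTS / "otu_filtered.tsv")
    env = io.read_env_profile(RESULTS / "environment.csv")

    diversity = stats.alpha_diversity_table(filtered)
    diversity.to_csv(RESULTS / "diversity.csv")

    frac = diversity.index.get_level_values("fraction").to_numpy()
    rows = []
    for index_name in ("richness", "chao1", "shannon", "simpson"):
        vals = diversity[index_name].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        method = "kruskal" if index_name == "simpson" else "anova"
        stat, p = stats.compare_groups(vals[ok], frac[ok], method)
        rows.append({"index": index_name, "grouping": "fraction",
                     "method": method, "statistic": stat, "p_value": p,
                     "stars": stats.significance_stars(p)})
    tests = pd.DataFrame(rows)
    tests.to_csv(RESULTS / "group_tests.csv", index=False)

    # chlorophyll is derived from the communities themselves, so it is
    # excluded from the explanatory factors
    env_x = env.drop(columns=["chl_a_ug_l"], errors="ignore")
    fcm_abund = (
        pd.read_csv(RESULTS / "fcm_summary.csv")
        .pivot(index="group", columns="depth_m", values="abundance_cells_per_ml")
    )
    vert = pd.read_csv(RESULTS / "vertical_profiles.csv", index_col=0)
    vert.columns = vert.columns.astype(float)

    for name, abund in (("fcm", fcm_abund), ("sm", vert)):
        corr = stats.pearson_env_correlation(abund, env_x)
        for part in ("r", "p", "stars"):
            corr[part].to_csv(RESULTS / f"correlation_{name}_{part}.csv")

    print(tests.to_string(index=False))


if __name__ == "__main__":
    main()
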