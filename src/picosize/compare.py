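"""Concordance between the two sizing routes and the end-to-end workflow.

The flow-cytometry route sizes whole populations from calibrated forward
scatter; the size-fractionation route ("SM") sizes taxon groups from the
distribution of their reads over filter fractions.  This module lines the
two up: the per-group diameter comparison with a "within mean ± sd"
agreement flag, the rank-correlation of vertical profiles, paired
environmental-correlation matrices, and a driver that runs the whole
simulate → gate → fractionate → count → compare pipeline and writes every
table plus a run manifest.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import __version__, fcm, io, sm, stats, synthetic
from .fractions import parse_fractions

FCM_GROUPS = list(fcm.POPULATIONS)


def compare_diameters(
    fcm_estimates: pd.DataFrame,
    sm_estimates: pd.Series,
    n_sd: float = 2.0,
) -> pd.DataFrame:
    """Tabulate FCM (mean ± sd) against SM point diameters per group.

    ``fcm_estimates`` needs columns ``mean`` and ``sd`` (μm) indexed by
    group; ``sm_estimates`` maps the same groups to SM diameters.  A
    group agrees when the SM estimate falls within mean ± ``n_sd``·sd;
    the default 2 sd reads the cytometric mean ± sd as a population
    size distribution and asks whether the SM point estimate lies in
    its central ~95% range.
    """
    if set(fcm_estimates.index) != set(sm_estimates.index):
        raise ValueError(
            "FCM and SM estimates must cover the same groups; got "
            f"{sorted(fcm_estimates.index)} vs {sorted(sm_estimates.index)}"
        )
    rows = []
    for g in fcm_estimates.index:
        m, s = float(fcm_estimates.loc[g, "mean"]), float(fcm_estimates.loc[g, "sd"])
        d_sm = float(sm_estimates.loc[g])
        rows.append(
            {
                "group": g,
                "fcm_mean_um": m,
                "fcm_sd_um": s,
                "sm_um": d_sm,
                "abs_diff_um": abs(d_sm - m),
                "rel_diff": abs(d_sm - m) / m if m else np.nan,
                "within_interval": bool(m - n_sd * s <= d_sm <= m + n_sd * s),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def profile_concordance(
    fcm_abund: pd.Series, sm_reads: pd.Series, group: str = ""
) -> dict:
    """Spearman rank agreement of two vertical profiles over shared depths.

    Read counts and cell abundances live on incommensurable scales, so
    only the depth ordering is compared.  Also reports whether both
    profiles peak at the same depth.
    """
    depths = sorted(set(fcm_abund.index) & set(sm_reads.index))
    if len(depths) < 3:
        raise ValueError("need at least 3 shared depths")
    x = fcm_abund.loc[depths].to_numpy(dtype=float)
    y = sm_reads.loc[depths].to_numpy(dtype=float)
    rho, p = spearmanr(x, y)
    return {
        "group": group,
        "spearman_rho": float(rho),
        "p_value": float(p),
        "n_depths": len(depths),
        "fcm_argmax_depth_m": float(depths[int(np.argmax(x))]),
        "sm_argmax_depth_m": float(depths[int(np.argmax(y))]),
        "same_argmax": bool(int(np.argmax(x)) == int(np.argmax(y))),
    }


# ---------------------------------------------------------------------------
# end-to-end workflow

DEFAULT_CONFIG: dict = {
    "simulate": {
        "n_events": 20_000,
        "n_cells": 100_000,
        "read_depth": 50_000,
        "analyzed_volume_ml": 0.1,
        "contaminants": True,
        "retention": {"steepness": 25.0, "ideal": False},
        "fsc_noise_sd": 0.05,
    },
    "gates": {"fl2_threshold": 50.0, "fl3_threshold": 5.0, "fsc_threshold": 128.0},
    "calibration": {"form": "log_linear", "k": 1.0, "d_ref": 0.6, "mfsc_ref": 100.0},
    "fractions": [0.2, 0.6, 1.2, 2.0],
    "filters": {"min_total_fraction": 5e-5, "min_confidence": 0.6},
    # raw pooling: the simulated design has equal per-sample read depth,
    # and raw counts are the convention behind published per-fraction
    # percentages; switch to "library" for designs with uneven depth.
    "stats": {"normalize": "raw"},
}


def _merged(config: dict | None) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def run_full_workflow(
    config: dict | None = None,
    out_dir: str | Path = "picosize_run",
    seed: int = synthetic.DEFAULT_SEED,
    write_events: bool = False,
) -> dict:
    """Simulate a survey and push it through both sizing routes.

    Writes the environmental table, OTU/taxonomy tables, per-depth FCM
    population summaries, the per-fraction size spectrum and SM
    diameters, diversity and group tests, paired environmental
    correlations, the diameter comparison and a JSON manifest into
    ``out_dir``.  Returns the in-memory artifacts keyed by name.
    Outputs are a pure function of (config, seed).
    """
    cfg = _merged(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scfg = cfg["simulate"]
    fractions = parse_fractions(cfg["fractions"])
    cal = fcm.CalibrationModel(
        d_ref=cfg["calibration"]["d_ref"],
        mfsc_ref=cfg["calibration"]["mfsc_ref"],
        form=cfg["calibration"]["form"],
        k=cfg["calibration"]["k"],
    )
    gates = fcm.GatingConfig(**cfg["gates"])
    retention = synthetic.RetentionModel(**scfg["retention"])

    # --- simulate -----------------------------------------------------
    truth = synthetic.default_community(seed=seed)
    truth = synthetic.CommunityTruth(
        taxa=truth.taxa, depths=truth.depths, fractions=fractions, seed=seed
    )
    if scfg["contaminants"]:
        truth = synthetic.with_contaminants(truth)
    env = synthetic.simulate_environment(truth.depths, seed=seed)
    otu, tax, captures = synthetic.simulate_dataset(
        truth,
        n_cells=scfg["n_cells"],
        read_depth=scfg["read_depth"],
        retention=retention,
        seed=seed,
    )

    events_by_depth = synthetic.simulate_event_series(
        truth,
        scfg["n_events"],
        analyzed_volume_ml=scfg["analyzed_volume_ml"],
        cal=cal,
        fsc_noise_sd=scfg["fsc_noise_sd"],
        seed=seed,
    )

    # --- flow-cytometry route -----------------------------------------
    fcm_rows = []
    for depth, ev in events_by_depth.items():
        labeled = fcm.gate_populations(ev, gates)
        # self-calibrates on this run's Prochlorococcus, keeping the form
        summary = fcm.population_summary(labeled, scfg["analyzed_volume_ml"], cal=cal)
        summary["depth_m"] = depth
        fcm_rows.append(summary.reset_index())
        if write_events:
            io.write_event_table(labeled, out / f"events_{depth:g}m.tsv")
    fcm_table = pd.concat(fcm_rows, ignore_index=True)

    # Table-2-style FCM diameters: mean from the pooled population MFSC,
    # dispersion from per-event calibrated diameters (the cytometric
    # mean ± sd convention)
    pooled = pd.concat(
        [fcm.gate_populations(ev, gates) for ev in events_by_depth.values()],
        ignore_index=True,
    )
    fcm_diam = fcm.pooled_diameter_table(pooled, cal=cal)
    fcm_abund = fcm_table.pivot(index="group", columns="depth_m", values="abundance_cells_per_ml")

    # --- size-fractionation route -------------------------------------
    filtered, flog = sm.filter_otus(
        otu,
        tax,
        min_total_fraction=cfg["filters"]["min_total_fraction"],
        min_confidence=cfg["filters"]["min_confidence"],
    )
    normalize = cfg["stats"]["normalize"]
    profiles = {}
    sm_diam = {}
    for g in FCM_GROUPS:
        prof = sm.fraction_proportions(
            filtered, tax, g, fractions=fractions, normalize=normalize
        )
        profiles[g] = prof
        sm_diam[g] = sm.estimate_diameter_sm(prof, fractions)
    profile_table = pd.DataFrame(profiles).T
    sm_diam = pd.Series(sm_diam, name="sm_um")
    vert = sm.vertical_profiles(filtered, tax, FCM_GROUPS, normalize=normalize)

    # --- statistics ----------------------------------------------------
    diversity = stats.alpha_diversity_table(filtered)
    test_rows = []
    frac_labels = diversity.index.get_level_values("fraction")
    for index_name in ("richness", "chao1", "shannon", "simpson"):
        vals = diversity[index_name].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        method = "kruskal" if index_name == "simpson" else "anova"
        stat, p = stats.compare_groups(vals[ok], frac_labels.to_numpy()[ok], method)
        test_rows.append(
            {"index": index_name, "grouping": "fraction", "method": method,
             "statistic": stat, "p_value": p}
        )
    group_tests = pd.DataFrame(test_rows)

    env_for_corr = env.drop(columns=["chl_a_ug_l"], errors="ignore")
    corr_fcm = stats.pearson_env_correlation(fcm_abund, env_for_corr)
    corr_sm = stats.pearson_env_correlation(vert, env_for_corr)

    # --- comparison ----------------------------------------------------
    comparison = compare_diameters(fcm_diam, sm_diam)
    concordance = pd.DataFrame(
        [
            profile_concordance(fcm_abund.loc[g], vert.loc[g], g)
            for g in FCM_GROUPS
        ]
    ).set_index("group")

    # --- write ----------------------------------------------------------
    io.write_env_profile(env, out / "environment.csv")
    io.write_otu_table(otu, out / "otu_raw.tsv")
    io.write_otu_table(filtered, out / "otu_filtered.tsv")
    io.write_taxonomy(tax, out / "taxonomy.tsv")
    fcm_table.to_csv(out / "fcm_summary.csv", index=False)
    profile_table.to_csv(out / "fraction_proportions.csv")
    sm_diam.to_frame().to_csv(out / "sm_diameters.csv")
    vert.to_csv(out / "vertical_profiles.csv")
    diversity.to_csv(out / "diversity.csv")
    group_tests.to_csv(out / "group_tests.csv", index=False)
    for name, mats in (("fcm", corr_fcm), ("sm", corr_sm)):
        for part in ("r", "p", "stars"):
            mats[part].to_csv(out / f"correlation_{name}_{part}.csv")
    comparison.to_csv(out / "diameter_comparison.csv")
    concordance.to_csv(out / "profile_concordance.csv")

    manifest = {
        "picosize_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": cfg,
        "n_otus_raw": int(otu.shape[0]),
        "n_otus_filtered": int(filtered.shape[0]),
        "otus_removed": {
            "low_abundance": flog.low_abundance,
            "low_confidence": flog.low_confidence,
            "excluded_lineage": flog.excluded_lineage,
            "unannotated": flog.unannotated,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "truth": truth,
        "env": env,
        "otu": otu,
        "taxonomy": tax,
        "filtered": filtered,
        "filter_log": flog,
        "captures": captures,
        "fcm_table": fcm_table,
        "fcm_diameters": fcm_diam,
        "fcm_abundance": fcm_abund,
        "fraction_proportions": profile_table,
        "sm_diameters": sm_diam,
        "vertical_profiles": vert,
        "diversity": diversity,
        "group_tests": group_tests,
        "correlation_fcm": corr_fcm,
        "correlation_sm": corr_sm,
        "comparison": comparison,
        "concordance": concordance,
        "manifest": manifest,
    }
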