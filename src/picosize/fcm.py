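"""Flow-cytometry gating, abundance, mean forward scatter and cell sizing.

Picophytoplankton events are classified into three populations from their
fluorescence and scatter signals: red fluorescence (FL3, chlorophyll)
separates phototrophs from noise; orange fluorescence (FL2, phycoerythrin)
isolates Synechococcus; forward scatter (FSC, a cell-size proxy) splits the
remaining chlorophyll-only events into small Prochlorococcus and larger
picoeukaryotes.  Population mean FSC (MFSC) is converted to a cell diameter
by calibration against the Prochlorococcus population, whose mean diameter
is taken as bead-equivalent at 0.6 μm.

Two calibration forms are provided:

``printed_power``
    d_cell = d_ref ** (MFSC_cell / MFSC_ref).  This is the empirical
    power form as commonly printed.  Note that for d_ref < 1 μm it is
    *decreasing* in MFSC, which inverts the physical expectation that
    larger cells scatter more; it is kept for fidelity and a warning is
    emitted when it is used.

``log_linear``
    d_cell = d_ref · exp(k · (MFSC_cell / MFSC_ref − 1)), a monotone
    increasing alternative with slope ``k`` in log-diameter per unit
    MFSC ratio.

Both forms satisfy d_cell = d_ref exactly when MFSC_cell = MFSC_ref.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

PROCHLOROCOCCUS = "Prochlorococcus"
SYNECHOCOCCUS = "Synechococcus"
PICOEUKARYOTE = "picoeukaryote"
UNCLASSIFIED = "unclassified"

#: Gated population labels, in gating-rule order.
POPULATIONS = (PROCHLOROCOCCUS, SYNECHOCOCCUS, PICOEUKARYOTE)

REQUIRED_COLUMNS = ("FSC", "FL2", "FL3")


@dataclass(frozen=True)
class GatingConfig:
    """Rectangular gating thresholds on the raw (or log) signal scale.

    fl3_threshold separates phototrophs from instrument noise and
    heterotrophs; fl2_threshold is the Synechococcus orange-fluorescence
    cut; fsc_threshold splits Prochlorococcus from picoeukaryotes.
    """

    fl2_threshold: float = 50.0
    fl3_threshold: float = 5.0
    fsc_threshold: float = 128.0
    log_transform: bool = False

    def __post_init__(self) -> None:
        if min(self.fl2_threshold, self.fl3_threshold, self.fsc_threshold) <= 0:
            raise ValueError("gating thresholds must be positive")


@dataclass(frozen=True)
class CalibrationModel:
    """FSC→diameter calibration anchored on the Prochlorococcus population.

    Parameters
    ----------
    d_ref:
        Bead-equivalent reference diameter (μm); the Prochlorococcus mean
        cell diameter, 0.6 μm by default.
    mfsc_ref:
        Mean FSC of the reference (Prochlorococcus) population, in the
        instrument's arbitrary units.
    form:
        ``"printed_power"`` or ``"log_linear"`` (see module docstring).
    k:
        Slope of the log_linear form (dimensionless).
    """

    d_ref: float = 0.6
    mfsc_ref: float = 100.0
    form: str = "printed_power"
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.d_ref <= 0 or self.mfsc_ref <= 0:
            raise ValueError("d_ref and mfsc_ref must be positive")
        if self.form not in ("printed_power", "log_linear"):
            raise ValueError(f"unknown calibration form: {self.form!r}")

    def diameter(self, mfsc_cell):
        """Cell diameter (μm) for a (population mean) FSC; vectorized."""
        scalar = np.isscalar(mfsc_cell)
        m = np.asarray(mfsc_cell, dtype=float)
        if np.any(m <= 0):
            raise ValueError("mfsc_cell must be positive")
        ratio = m / self.mfsc_ref
        if self.form == "printed_power":
            if self.d_ref < 1.0 and not np.allclose(ratio, 1.0):
                warnings.warn(
                    "printed_power calibration is decreasing in MFSC for "
                    "d_ref < 1 μm; consider form='log_linear'",
                    stacklevel=2,
                )
            d = self.d_ref ** ratio
        else:
            d = self.d_ref * np.exp(self.k * (ratio - 1.0))
        return float(d) if scalar else d

    def mfsc(self, diameter) -> np.ndarray:
        """Exact inverse: the mean FSC that maps back to ``diameter``.

        Used by the event simulator so that gated-population sizing is
        testable against known truth.  Vectorized over ``diameter``.
        """
        d = np.asarray(diameter, dtype=float)
        if np.any(d <= 0):
            raise ValueError("diameters must be positive")
        if self.form == "printed_power":
            return self.mfsc_ref * np.log(d) / np.log(self.d_ref)
        return self.mfsc_ref * (1.0 + np.log(d / self.d_ref) / self.k)


def _require_columns(events: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing columns: {missing}")


def gate_populations(events: pd.DataFrame, config: GatingConfig | None = None) -> pd.DataFrame:
    """Assign each event exactly one population label.

    Rule order: events below the FL3 (red fluorescence) threshold are
    unclassified noise; of the rest, FL2 at or above threshold gates
    Synechococcus; the remaining chlorophyll-only events split on FSC into
    Prochlorococcus (below) and picoeukaryotes (at or above).

    Returns a copy of ``events`` with a ``label`` column.
    """
    config = config or GatingConfig()
    _require_columns(events)
    fsc, fl2, fl3 = (events[c].to_numpy(dtype=float) for c in REQUIRED_COLUMNS)
    if config.log_transform:
        with np.errstate(divide="ignore"):
            fsc, fl2, fl3 = np.log10(fsc), np.log10(fl2), np.log10(fl3)
        t_fl2, t_fl3, t_fsc = (
            math.log10(config.fl2_threshold),
            math.log10(config.fl3_threshold),
            math.log10(config.fsc_threshold),
        )
    else:
        t_fl2, t_fl3, t_fsc = (
            config.fl2_threshold,
            config.fl3_threshold,
            config.fsc_threshold,
        )

    label = np.full(len(events), UNCLASSIFIED, dtype=object)
    photo = fl3 >= t_fl3
    syn = photo & (fl2 >= t_fl2)
    proc = photo & ~syn & (fsc < t_fsc)
    peuk = photo & ~syn & ~proc
    label[syn] = SYNECHOCOCCUS
    label[proc] = PROCHLOROCOCCUS
    label[peuk] = PICOEUKARYOTE

    out = events.copy()
    out["label"] = label
    return out


def compute_abundance(labeled: pd.DataFrame, analyzed_volume_ml: float) -> dict[str, float]:
    """Cells per mL for each gated population: count / analysed volume."""
    if analyzed_volume_ml <= 0:
        raise ValueError("analyzed volume must be positive")
    counts = labeled["label"].value_counts()
    return {g: float(counts.get(g, 0)) / analyzed_volume_ml for g in POPULATIONS}


def compute_mfsc(labeled: pd.DataFrame) -> dict[str, float]:
    """Arithmetic mean FSC per gated population.

    Populations with no events are absent from the result (not zero):
    a missing population has no mean scatter, and reporting 0 would
    corrupt downstream sizing.
    """
    _require_columns(labeled)
    out: dict[str, float] = {}
    for g in POPULATIONS:
        sub = labeled.loc[labeled["label"] == g, "FSC"]
        if len(sub):
            out[g] = float(sub.mean())
    return out


def estimate_diameter_fcm(mfsc_cell: float, cal: CalibrationModel) -> float:
    """Bead-calibrated diameter (μm) from a population's mean FSC."""
    return cal.diameter(mfsc_cell)


def population_summary(
    labeled: pd.DataFrame,
    analyzed_volume_ml: float,
    cal: CalibrationModel | None = None,
    self_calibrate: bool = True,
) -> pd.DataFrame:
    """Per-population abundance, mean FSC and diameter for one depth's run.

    With ``self_calibrate`` (default) the calibration reference MFSC is
    taken from this run's gated Prochlorococcus population (the
    bead-equivalence assumption); ``cal`` then only supplies the form,
    slope and reference diameter.  Pass ``self_calibrate=False`` to use
    ``cal`` exactly as given.
    """
    abund = compute_abundance(labeled, analyzed_volume_ml)
    mfsc = compute_mfsc(labeled)
    cal = cal or CalibrationModel()
    if self_calibrate:
        if PROCHLOROCOCCUS not in mfsc:
            raise ValueError(
                "no Prochlorococcus events to self-calibrate on; "
                "pass an explicit CalibrationModel with self_calibrate=False"
            )
        cal = replace(cal, mfsc_ref=mfsc[PROCHLOROCOCCUS])
    rows = []
    for g in POPULATIONS:
        m = mfsc.get(g)
        rows.append(
            {
                "group": g,
                "abundance_cells_per_ml": abund[g],
                "mean_fsc": m if m is not None else np.nan,
                "diameter_um": cal.diameter(m) if m is not None else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def pooled_diameter_table(
    labeled: pd.DataFrame,
    cal: CalibrationModel | None = None,
    self_calibrate: bool = True,
) -> pd.DataFrame:
    """Survey-wide population diameters as mean ± sd (μm).

    Events pooled across runs give one table per population: ``mean``
    from the pooled population MFSC and ``sd`` from the spread of
    per-event calibrated diameters — the cytometric mean ± sd
    convention.  Self-calibration anchors the reference MFSC on the
    pooled Prochlorococcus population, as in :func:`population_summary`.
    """
    _require_columns(labeled)
    mfsc = compute_mfsc(labeled)
    cal = cal or CalibrationModel()
    if self_calibrate:
        if PROCHLOROCOCCUS not in mfsc:
            raise ValueError(
                "no Prochlorococcus events to self-calibrate on; "
                "pass an explicit CalibrationModel with self_calibrate=False"
            )
        cal = replace(cal, mfsc_ref=mfsc[PROCHLOROCOCCUS])
    rows = {}
    for g in POPULATIONS:
        if g not in mfsc:
            continue
        per_event = cal.diameter(
            labeled.loc[labeled["label"] == g, "FSC"].to_numpy()
        )
        rows[g] = {
            "mean": float(cal.diameter(mfsc[g])),
            "sd": float(np.std(per_event, ddof=1)),
        }
    out = pd.DataFrame(rows).T.rename_axis("group")
    return out.loc[[g for g in POPULATIONS if g in out.index]]
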