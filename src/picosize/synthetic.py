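"""Ground-truthed synthetic inputs: FCM event tables, size-fractionated
OTU count tables, taxonomy and environmental depth profiles.

The generator emulates a tropical oligotrophic euphotic-zone study
design: six depths (5, 25, 50, 113 = deep chlorophyll maximum, 150,
200 m), serial filtration through 2.0 / 1.2 / 0.6 / 0.2 μm pores giving
three pico size fractions, and two marker genes (plastid-biased 16S for
the cyanobacteria, 18S V4 for picoeukaryotes).

Model components
----------------
* Each taxon carries a log-normal cell-diameter distribution (median μm,
  log-sd), a relative-abundance profile over depth (surface-maximum,
  DCM-maximum or deep types), a marker-copy weight per cell, a
  fragility — the probability that a cell fragments during filtration
  and sheds material into the smallest fraction — and log-normal
  fluorescence signal parameters.
* Filter retention is logistic in log(diameter / pore size) with a
  configurable steepness, so cells slightly larger than a pore can pass
  (the non-ideal sieving that real track-etched membranes show);
  ``ideal=True`` collapses it to a step function.
* Event FSC is the exact inverse of the flow-cytometry calibration the
  analysis is configured with, plus multiplicative log-normal noise, so
  diameter recovery is testable end to end.
* Reads are multinomial draws per (depth, fraction, marker) sample with
  taxon weights = captured cell weight × marker copy number.

Everything is reproducible bit for bit under a fixed seed; the default
seed 20181104 (the cruise date of the emulated survey) is recorded on
the truth object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fcm import CalibrationModel
from .fractions import DEFAULT_FRACTIONS, PREFILTER_PORE_UM, SizeFraction

DEFAULT_DEPTHS_M: tuple[float, ...] = (5, 25, 50, 113, 150, 200)
DEFAULT_SEED = 20181104

#: Calibration the simulator inverts unless told otherwise.  The monotone
#: log-linear form is the default so that simulated FSC grows with cell
#: size, as physical forward scatter does.
DEFAULT_CALIBRATION = CalibrationModel(
    d_ref=0.6, mfsc_ref=100.0, form="log_linear", k=1.0
)

PICOEUKARYOTE_TAXON = "picoeukaryote_taxon"
_GATING_LABEL = {
    "Prochlorococcus": "Prochlorococcus",
    "Synechococcus": "Synechococcus",
    PICOEUKARYOTE_TAXON: "picoeukaryote",
}


@dataclass(frozen=True)
class FluorParams:
    """Log-normal fluorescence parameters (natural-log scale, a.u.)."""

    log_fl2_mean: float
    log_fl3_mean: float
    log_fl2_sd: float = 0.3
    log_fl3_sd: float = 0.3


@dataclass(frozen=True)
class TaxonSpec:
    """One simulated taxon: its sizes, depth structure and signals."""

    name: str
    group: str  # Prochlorococcus | Synechococcus | picoeukaryote_taxon | excluded
    marker: str  # "16S" | "18S"
    size_median_um: float
    size_log_sd: float
    depth_profile: tuple[float, ...]
    fluor: FluorParams
    copy_number: float = 1.0
    fragility: float = 0.0
    lineage: str = ""
    confidence: float = 0.95
    #: Debris material (broken cells, metazoan fragments, shed plastids)
    #: deposits on the filters by clogging/adsorption rather than sieving,
    #: so it is captured uniformly across fractions regardless of the
    #: nominal particle size.  Debris taxa emit no FCM events.
    debris: bool = False

    def __post_init__(self) -> None:
        if self.size_median_um <= 0:
            raise ValueError(f"{self.name}: size median must be positive")
        if any(w < 0 for w in self.depth_profile) or not any(self.depth_profile):
            raise ValueError(f"{self.name}: depth profile must be ≥0, not all 0")
        if not 0 <= self.fragility <= 1:
            raise ValueError(f"{self.name}: fragility must lie in [0, 1]")
        if self.copy_number < 0:
            raise ValueError(f"{self.name}: copy number must be ≥ 0")

    def draw_diameters(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.size_median_um * np.exp(
            rng.normal(0.0, self.size_log_sd, size=n)
        )


@dataclass(frozen=True)
class RetentionModel:
    """Probability a cell of diameter d is retained by a pore.

    Logistic in log(d / pore): p = (d/pore)^s / (1 + (d/pore)^s), which
    is 1/2 at d = pore and sharpens with steepness s; ``ideal=True``
    gives the step function 1{d ≥ pore}.
    """

    steepness: float = 25.0
    ideal: bool = False

    def retention_probability(self, diameter, pore_um: float) -> np.ndarray:
        d = np.asarray(diameter, dtype=float)
        if self.ideal:
            return (d >= pore_um).astype(float)
        z = self.steepness * np.log(d / pore_um)
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class CommunityTruth:
    """Simulator ground truth for a depth-resolved community."""

    taxa: tuple[TaxonSpec, ...]
    depths: tuple[float, ...] = DEFAULT_DEPTHS_M
    fractions: tuple[SizeFraction, ...] = DEFAULT_FRACTIONS
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if any(d2 <= d1 for d1, d2 in zip(self.depths, self.depths[1:])):
            raise ValueError("depths must be strictly increasing")
        for f1, f2 in zip(self.fractions, self.fractions[1:]):
            if f2.lower < f1.upper:
                raise ValueError("fractions must be ordered and non-overlapping")
        for t in self.taxa:
            if len(t.depth_profile) != len(self.depths):
                raise ValueError(
                    f"{t.name}: depth profile length {len(t.depth_profile)} "
                    f"!= {len(self.depths)} depths"
                )

    def depth_index(self, depth: float) -> int:
        if depth not in self.depths:
            raise ValueError(f"depth {depth} m is not a configured depth")
        return self.depths.index(depth)

    def taxon_weights_at(self, depth: float) -> np.ndarray:
        """Relative cell abundance of each taxon at one depth."""
        i = self.depth_index(depth)
        w = np.array([t.depth_profile[i] for t in self.taxa], dtype=float)
        return w / w.sum()


# ---------------------------------------------------------------------------
# environment

_ENV_ANCHORS = {
    # (value at 5 m, value at 200 m); linear in depth in between
    "temperature_c": (29.1, 15.7),
    "salinity": (34.2, 35.0),
    "din_umol_l": (0.42, 8.02),
    "dsi_umol_l": (0.53, 4.65),
    "dip_umol_l": (0.08, 0.33),
}
_CHL_MAX_UG_L = 0.49
_CHL_PEAK_DEPTH_M = 113.0
_CHL_PEAK_WIDTH_M = 35.0
_REF_DEPTH_RANGE = (5.0, 200.0)


def simulate_environment(
    depths=DEFAULT_DEPTHS_M,
    seed: int = DEFAULT_SEED,
    noise: float = 0.0,
    anchors: dict | None = None,
) -> pd.DataFrame:
    """Environmental covariates per depth, indexed by depth (m).

    Temperature decreases and nutrients (DIN, DIP, DSi) increase
    monotonically with depth between anchor values at 5 and 200 m
    (defaults span the emulated station's observed ranges: 29.1→15.7 °C,
    DIN 0.42→8.02, DSi 0.53→4.65, DIP 0.08→0.33 μmol L⁻¹); chlorophyll a
    is a Gaussian bump peaking at the 113 m DCM (0.49 μg L⁻¹).  ``noise``
    adds small seeded relative jitter (0 = exact anchors).
    """
    depths = tuple(float(d) for d in depths)
    if not depths or any(d2 <= d1 for d1, d2 in zip(depths, depths[1:])):
        raise ValueError("depths must be non-empty and strictly increasing")
    anchors = {**_ENV_ANCHORS, **(anchors or {})}
    lo, hi = _REF_DEPTH_RANGE
    z = np.clip((np.array(depths) - lo) / (hi - lo), 0.0, 1.0)

    rng = np.random.default_rng(seed)
    cols = {}
    for name, (top, bottom) in anchors.items():
        base = top + (bottom - top) * z
        if noise:
            base = base * np.exp(rng.normal(0.0, noise, size=len(depths)))
        cols[name] = base
    chl = _CHL_MAX_UG_L * np.exp(
        -0.5 * ((np.array(depths) - _CHL_PEAK_DEPTH_M) / _CHL_PEAK_WIDTH_M) ** 2
    )
    if noise:
        chl = chl * np.exp(rng.normal(0.0, noise, size=len(depths)))
    cols["chl_a_ug_l"] = chl
    out = pd.DataFrame(cols, index=pd.Index(depths, name="depth_m"))
    return out


# ---------------------------------------------------------------------------
# flow-cytometry events

def simulate_fcm_events(
    truth: CommunityTruth,
    depth: float,
    n_events: int,
    analyzed_volume_ml: float = 0.1,
    seed: int | None = None,
    cal: CalibrationModel = DEFAULT_CALIBRATION,
    fsc_noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Per-event FSC/FL2/FL3 signals with retained ground-truth labels.

    Taxa are drawn proportional to their depth profile at ``depth``; each
    event's FSC is the exact inverse of ``cal`` at its drawn diameter,
    times log-normal noise of log-sd ``fsc_noise_sd``.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    taxa = [t for t in truth.taxa if t.group in _GATING_LABEL]
    i = truth.depth_index(depth)
    w = np.array([t.depth_profile[i] for t in taxa], dtype=float)
    w = w / w.sum()
    which = rng.choice(len(taxa), size=n_events, p=w)

    fsc = np.empty(n_events)
    fl2 = np.empty(n_events)
    fl3 = np.empty(n_events)
    diam = np.empty(n_events)
    for j, t in enumerate(taxa):
        m = which == j
        k = int(m.sum())
        if k == 0:
            continue
        d = t.draw_diameters(k, rng)
        diam[m] = d
        noise = np.exp(rng.normal(0.0, fsc_noise_sd, size=k)) if fsc_noise_sd else 1.0
        fsc[m] = cal.mfsc(d) * noise
        fl2[m] = np.exp(rng.normal(t.fluor.log_fl2_mean, t.fluor.log_fl2_sd, size=k))
        fl3[m] = np.exp(rng.normal(t.fluor.log_fl3_mean, t.fluor.log_fl3_sd, size=k))

    out = pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "FSC": fsc,
            "FL2": fl2,
            "FL3": fl3,
            "true_diameter_um": diam,
            "true_taxon": [taxa[j].name for j in which],
            "true_label": [_GATING_LABEL[taxa[j].group] for j in which],
        }
    )
    out.attrs["depth_m"] = depth
    out.attrs["analyzed_volume_ml"] = analyzed_volume_ml
    return out


def simulate_event_series(
    truth: CommunityTruth,
    n_events_peak: int,
    analyzed_volume_ml: float = 0.1,
    cal: CalibrationModel = DEFAULT_CALIBRATION,
    fsc_noise_sd: float = 0.05,
    seed: int | None = None,
    min_events: int = 1000,
) -> dict[float, pd.DataFrame]:
    """Per-depth event tables with depth-proportional event counts.

    A fixed analysed volume sees event counts proportional to the total
    gated-cell concentration at each depth: the busiest depth yields
    ``n_events_peak`` events and no depth fewer than ``min_events``.
    Depths receive independent sub-streams of ``seed``.
    """
    gating_taxa = [t for t in truth.taxa if t.group in _GATING_LABEL]
    totals = {
        d: sum(t.depth_profile[i] for t in gating_taxa)
        for i, d in enumerate(truth.depths)
    }
    peak = max(totals.values())
    root = np.random.SeedSequence(
        truth.seed if seed is None else seed
    ).spawn(len(truth.depths))
    out: dict[float, pd.DataFrame] = {}
    for depth, ss in zip(truth.depths, root):
        out[depth] = simulate_fcm_events(
            truth,
            depth,
            max(min_events, round(n_events_peak * totals[depth] / peak)),
            analyzed_volume_ml=analyzed_volume_ml,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            cal=cal,
            fsc_noise_sd=fsc_noise_sd,
        )
    return out


# ---------------------------------------------------------------------------
# serial filtration

@dataclass
class FractionationResult:
    """Outcome of pushing one depth's cells through the filter stack.

    ``weights``: read-weight per (taxon × fraction) — equal to captured
    cell counts when no taxon is fragile, fractional otherwise, because a
    fragmenting cell splits its unit weight between its capture fraction
    and the smallest fraction.
    ``accounting``: integer cell bookkeeping per taxon; for every taxon
    captured + passed_through + discarded_prefilter = n_cells exactly.
    """

    weights: pd.DataFrame
    accounting: pd.DataFrame

    def conserved(self) -> bool:
        a = self.accounting
        return bool(
            (
                a["captured"] + a["passed_through"] + a["discarded_prefilter"]
                == a["n_cells"]
            ).all()
        )


def simulate_fractionation(
    truth: CommunityTruth,
    depth: float,
    n_cells: int,
    retention: RetentionModel | None = None,
    seed: int | None = None,
    frag_split: float = 0.5,
) -> FractionationResult:
    """Serial filtration of ``n_cells`` cells drawn from the community.

    Each cell first meets the 2.0 μm pre-filter (retained → discarded
    from the pico dataset), then the fraction filters in decreasing pore
    order; it is captured by the first filter whose retention draw
    succeeds, or passes through the 0.2 μm filter entirely.  A captured
    cell of a fragile taxon fragments with probability ``fragility``,
    moving ``frag_split`` of its unit read weight into the smallest
    fraction.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if not 0 <= frag_split <= 1:
        raise ValueError("frag_split must lie in [0, 1]")
    retention = retention or RetentionModel()
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    taxa = truth.taxa
    n_per_taxon = rng.multinomial(n_cells, truth.taxon_weights_at(depth))
    fracs = truth.fractions
    labels = [f.label for f in fracs]
    smallest = labels[0]
    # filters in capture order: largest pore first
    pores = [f.lower for f in reversed(fracs)]
    pore_label = {f.lower: f.label for f in fracs}

    weights = pd.DataFrame(0.0, index=[t.name for t in taxa], columns=labels)
    acct = pd.DataFrame(
        0,
        index=[t.name for t in taxa],
        columns=["n_cells", "captured", "passed_through", "discarded_prefilter"],
    )

    for t, n in zip(taxa, n_per_taxon):
        acct.loc[t.name, "n_cells"] = int(n)
        if n == 0:
            continue
        if t.debris:
            # non-sieving deposition: uniform over the fraction filters
            hit = rng.integers(0, len(labels), size=int(n))
            for j, lab in enumerate(labels):
                weights.loc[t.name, lab] += float((hit == j).sum())
            acct.loc[t.name, "captured"] = int(n)
            continue
        d = t.draw_diameters(int(n), rng)
        alive = rng.random(int(n)) >= retention.retention_probability(
            d, PREFILTER_PORE_UM
        )
        acct.loc[t.name, "discarded_prefilter"] = int((~alive).sum())

        captured_label = np.full(int(n), "", dtype=object)
        for pore in pores:
            p = retention.retention_probability(d, pore)
            caught = alive & (rng.random(int(n)) < p)
            captured_label[caught] = pore_label[pore]
            alive = alive & ~caught
        acct.loc[t.name, "passed_through"] = int(alive.sum())
        captured = captured_label != ""
        acct.loc[t.name, "captured"] = int(captured.sum())

        frag = captured & (rng.random(int(n)) < t.fragility)
        for lab in labels:
            whole = (captured_label == lab) & ~frag
            broken = (captured_label == lab) & frag
            w = float(whole.sum())
            if broken.any():
                k = float(broken.sum())
                w += (1.0 - frag_split) * k
                weights.loc[t.name, smallest] += frag_split * k
            weights.loc[t.name, lab] += w

    return FractionationResult(weights=weights, accounting=acct)


# ---------------------------------------------------------------------------
# read sampling

def simulate_reads(
    fraction_weights: pd.DataFrame,
    read_depth: int,
    truth: CommunityTruth,
    seed: int | None = None,
    depth: float = 0.0,
) -> pd.DataFrame:
    """Multinomial read counts per (depth, fraction, marker) sample.

    For each fraction and marker, reads are a multinomial draw of size
    ``read_depth`` over that marker's taxa with weights = captured cell
    weight × copy number; every non-empty sample column sums exactly to
    ``read_depth``.  Samples with zero total weight yield an all-zero
    column and a warning.
    """
    if read_depth <= 0:
        raise ValueError("read_depth must be positive")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    markers = sorted({t.marker for t in truth.taxa})
    by_name = {t.name: t for t in truth.taxa}
    cols = {}
    for frac in fraction_weights.columns:
        for marker in markers:
            names = [n for n in fraction_weights.index if by_name[n].marker == marker]
            w = np.array(
                [fraction_weights.loc[n, frac] * by_name[n].copy_number for n in names]
            )
            counts = np.zeros(len(fraction_weights.index), dtype=int)
            if w.sum() > 0:
                draw = rng.multinomial(read_depth, w / w.sum())
                for n, c in zip(names, draw):
                    counts[fraction_weights.index.get_loc(n)] = c
            else:
                warnings.warn(
                    f"sample ({depth} m, {frac}, {marker}) has zero weight; "
                    "emitting an empty column",
                    stacklevel=2,
                )
            cols[(depth, frac, marker)] = counts
    table = pd.DataFrame(cols, index=fraction_weights.index)
    table.columns = pd.MultiIndex.from_tuples(cols.keys(), names=("depth", "fraction", "marker"))
    table.index.name = "otu_id"
    return table


# ---------------------------------------------------------------------------
# whole designs

def taxonomy_table(truth: CommunityTruth) -> pd.DataFrame:
    """Taxonomy rows (lineage, confidence, analysis group, marker) per OTU."""
    rows = []
    for t in truth.taxa:
        group = t.group if t.group != PICOEUKARYOTE_TAXON else t.name
        rows.append(
            {
                "otu_id": t.name,
                "lineage": t.lineage,
                "confidence": t.confidence,
                "group": group if t.group != "excluded" else "excluded",
                "marker": t.marker,
            }
        )
    return pd.DataFrame(rows).set_index("otu_id")


def simulate_dataset(
    truth: CommunityTruth,
    n_cells: int = 100_000,
    read_depth: int = 50_000,
    retention: RetentionModel | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[float, FractionationResult]]:
    """Full size-fractionated sequencing design over all configured depths.

    Returns the combined OTU table (OTU × (depth, fraction, marker)),
    the taxonomy table, and the per-depth filtration ground truth.
    """
    root = np.random.SeedSequence(truth.seed if seed is None else seed)
    per_depth = root.spawn(len(truth.depths))
    tables = []
    captures: dict[float, FractionationResult] = {}
    for depth, ss in zip(truth.depths, per_depth):
        s1, s2 = ss.spawn(2)
        res = simulate_fractionation(
            truth, depth, n_cells, retention, seed=s1.generate_state(1)[0] % (2**31)
        )
        captures[depth] = res
        tables.append(
            simulate_reads(
                res.weights,
                read_depth,
                truth,
                seed=s2.generate_state(1)[0] % (2**31),
                depth=depth,
            )
        )
    otu = pd.concat(tables, axis=1)
    return otu, taxonomy_table(truth), captures


# ---------------------------------------------------------------------------
# stock communities

def _fluor(group: str) -> FluorParams:
    if group == "Synechococcus":
        return FluorParams(np.log(500.0), np.log(100.0))
    if group == "Prochlorococcus":
        return FluorParams(np.log(5.0), np.log(50.0))
    return FluorParams(np.log(5.0), np.log(500.0))


def default_community(
    depths: tuple[float, ...] = DEFAULT_DEPTHS_M, seed: int = DEFAULT_SEED
) -> CommunityTruth:
    """A realistic oligotrophic euphotic-zone picophytoplankton community.

    Prochlorococcus dominates with a DCM maximum; Synechococcus peaks at
    the surface and fades with depth; the picoeukaryotes cover the main
    classes observed in such columns (a haptophyte, a fragile
    cryptophyte, a deep pelagophyte, a mamiellophyte and a high-copy
    dinoflagellate), mostly accumulating at the DCM.  Sizes are
    log-normal with field-plausible medians (0.6 μm Prochlorococcus,
    0.9 μm Synechococcus, 1.0–1.6 μm picoeukaryotes).
    """
    if len(depths) != len(DEFAULT_DEPTHS_M):
        raise ValueError("default_community expects the six standard depths")
    mk = TaxonSpec
    taxa = (
        mk(
            "Prochlorococcus", "Prochlorococcus", "16S", 0.6, 0.15,
            (9.0, 11.0, 15.0, 20.0, 5.0, 0.8), _fluor("Prochlorococcus"),
            copy_number=1.0,
            lineage="d__Bacteria;p__Cyanobacteria;c__Cyanophyceae;"
            "o__Synechococcales;f__Prochlorococcaceae;g__Prochlorococcus",
            confidence=0.99,
        ),
        mk(
            "Synechococcus", "Synechococcus", "16S", 0.9, 0.12,
            (3.0, 2.4, 1.4, 0.55, 0.12, 0.03), _fluor("Synechococcus"),
            copy_number=2.0,
            lineage="d__Bacteria;p__Cyanobacteria;c__Cyanophyceae;"
            "o__Synechococcales;f__Synechococcaceae;g__Synechococcus",
            confidence=0.99,
        ),
        mk(
            "Chrysochromulina", PICOEUKARYOTE_TAXON, "18S", 1.4, 0.15,
            (1.0, 0.8, 0.9, 0.6, 0.2, 0.05), _fluor("picoeukaryote"),
            copy_number=3.0,
            lineage="d__Eukaryota;p__Haptophyta;c__Prymnesiophyceae;"
            "o__Prymnesiales;f__Chrysochromulinaceae;g__Chrysochromulina",
            confidence=0.95,
        ),
        mk(
            "Hemiselmis", PICOEUKARYOTE_TAXON, "18S", 1.5, 0.12,
            (0.2, 0.3, 0.5, 1.0, 0.3, 0.05), _fluor("picoeukaryote"),
            copy_number=3.0, fragility=0.5,
            lineage="d__Eukaryota;p__Cryptophyta;c__Cryptophyceae;"
            "o__Pyrenomonadales;f__Chroomonadaceae;g__Hemiselmis",
            confidence=0.93,
        ),
        mk(
            "Pelagomonas", PICOEUKARYOTE_TAXON, "18S", 1.0, 0.12,
            (0.02, 0.03, 0.08, 1.0, 0.8, 0.5), _fluor("picoeukaryote"),
            copy_number=2.0,
            lineage="d__Eukaryota;p__Ochrophyta;c__Pelagophyceae;"
            "o__Pelagomonadales;f__Pelagomonadaceae;g__Pelagomonas",
            confidence=0.94,
        ),
        mk(
            "Micromonas", PICOEUKARYOTE_TAXON, "18S", 1.0, 0.15,
            (0.5, 0.6, 0.7, 1.0, 0.1, 0.02), _fluor("picoeukaryote"),
            copy_number=2.0,
            lineage="d__Eukaryota;p__Chlorophyta;c__Mamiellophyceae;"
            "o__Mamiellales;f__Mamiellaceae;g__Micromonas",
            confidence=0.96,
        ),
        mk(
            "Gymnodiniales_sp", PICOEUKARYOTE_TAXON, "18S", 1.6, 0.12,
            (0.2, 0.3, 0.5, 1.0, 0.3, 0.1), _fluor("picoeukaryote"),
            copy_number=6.0, fragility=0.1,
            lineage="d__Eukaryota;p__Dinoflagellata;c__Dinophyceae;"
            "o__Gymnodiniales;f__Gymnodiniaceae;g__Gymnodiniales_sp",
            confidence=0.90,
        ),
        # Background material that competes for reads in every library.
        # Amplicon libraries are never purely picophytoplankton: plastid
        # 16S primers also amplify larger phytoplankton debris, and 18S
        # libraries carry metazoan and other non-pico DNA.  Because the
        # per-sample read depth is fixed, it is this fraction-uniform
        # background that lets a group's read counts track its captured
        # biomass across filters.
        mk(
            "nano_plastid_debris", "background", "16S", 1.0, 0.3,
            (30.0,) * 6, _fluor("picoeukaryote"),
            copy_number=1.0, debris=True,
            lineage="d__Bacteria;p__Cyanobacteria;c__Bacillariophyceae_plastid;"
            "o__Bacillariales;g__Chaetoceros_plastid",
            confidence=0.9,
        ),
        mk(
            "metazoan_debris", "background", "18S", 1.0, 0.3,
            (40.0,) * 6, _fluor("picoeukaryote"),
            copy_number=3.0, debris=True,
            lineage="d__Eukaryota;p__Metazoa;c__Hexanauplia;o__Calanoida",
            confidence=0.92,
        ),
    )
    return CommunityTruth(taxa=taxa, depths=depths, seed=seed)


def with_contaminants(truth: CommunityTruth) -> CommunityTruth:
    """Add nuisance OTUs that the downstream filter must remove.

    Includes an archaeon, a fungus, a copepod (zooplankton), a
    low-confidence annotation, an unannotated OTU and a genuinely rare
    OTU (below the 0.005% abundance rule at typical read depths).
    """
    flat = tuple(0.01 for _ in truth.depths)
    pico_fluor = _fluor("picoeukaryote")
    extras = (
        TaxonSpec(
            "Marine_Group_II", "excluded", "16S", 0.5, 0.1, flat, pico_fluor,
            lineage="d__Archaea;p__Thermoplasmatota;c__Thermoplasmata;"
            "o__Marine_Group_II", confidence=0.97,
        ),
        TaxonSpec(
            "Metschnikowia", "excluded", "18S", 1.8, 0.1, flat, pico_fluor,
            lineage="d__Eukaryota;p__Fungi;c__Saccharomycetes;"
            "g__Metschnikowia", confidence=0.91,
        ),
        TaxonSpec(
            "Oithona", "excluded", "18S", 1.9, 0.1, flat, pico_fluor,
            lineage="d__Eukaryota;p__Metazoa;c__Hexanauplia;g__Oithona",
            confidence=0.95,
        ),
        TaxonSpec(
            "uncertain_stramenopile", "excluded", "18S", 1.2, 0.1, flat,
            pico_fluor,
            lineage="d__Eukaryota;p__Ochrophyta;c__unclassified",
            confidence=0.4,
        ),
        TaxonSpec(
            "dark_matter", "excluded", "18S", 1.1, 0.1, flat, pico_fluor,
            lineage="", confidence=0.0,
        ),
        TaxonSpec(
            "rare_prasinophyte", PICOEUKARYOTE_TAXON, "18S", 1.0, 0.1,
            tuple(1e-5 for _ in truth.depths), pico_fluor,
            lineage="d__Eukaryota;p__Chlorophyta;c__Prasinophyceae;"
            "g__Prasinoderma", confidence=0.92,
        ),
    )
    return replace(truth, taxa=truth.taxa + extras)


def well_separated_community(
    depths: tuple[float, ...] = DEFAULT_DEPTHS_M, seed: int = DEFAULT_SEED
) -> CommunityTruth:
    """Three-taxon community with tight, well-separated size and signal
    distributions — the controlled setting for recovery experiments."""
    flat_dcm = (0.6, 0.7, 0.9, 1.0, 0.5, 0.2)
    surface = (1.0, 0.8, 0.5, 0.3, 0.1, 0.05)
    if len(depths) != len(DEFAULT_DEPTHS_M):
        flat_dcm = tuple(1.0 for _ in depths)
        surface = tuple(1.0 for _ in depths)
    taxa = (
        TaxonSpec(
            "Prochlorococcus", "Prochlorococcus", "16S", 0.6, 0.08,
            flat_dcm, _fluor("Prochlorococcus"),
            lineage="d__Bacteria;p__Cyanobacteria;g__Prochlorococcus",
            confidence=0.99,
        ),
        TaxonSpec(
            "Synechococcus", "Synechococcus", "16S", 0.9, 0.08,
            surface, _fluor("Synechococcus"), copy_number=1.0,
            lineage="d__Bacteria;p__Cyanobacteria;g__Synechococcus",
            confidence=0.99,
        ),
        TaxonSpec(
            "Ostreococcus", PICOEUKARYOTE_TAXON, "18S", 1.6, 0.08,
            flat_dcm, _fluor("picoeukaryote"),
            lineage="d__Eukaryota;p__Chlorophyta;c__Mamiellophyceae;"
            "g__Ostreococcus", confidence=0.97,
        ),
    )
    return CommunityTruth(taxa=taxa, depths=depths, seed=seed)
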