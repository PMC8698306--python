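"""Size-fractionated amplicon ("SM") pipeline: OTU filtering, per-fraction
size spectra, the midpoint-weighted diameter estimate, vertical read
profiles and composition summaries.

The central quantity is the per-fraction read proportion N% of a taxon
group: the share of the group's reads captured on each of the three
filters (0.2–0.6, 0.6–1.2, 1.2–2 μm).  The group's SM diameter is the
proportion-weighted mean of the fraction midpoints,

    d_SM = Σ_f  (Range_min_f + Range_max_f)/2 · N%_f ,

which is bounded by the extreme midpoints (0.4 and 1.6 μm for the
default design) and increases monotonically as read mass shifts toward
larger fractions.

OTU tables are pandas DataFrames with OTU ids as the row index and a
three-level column MultiIndex (depth [m], fraction label, marker gene).
Taxonomy tables are DataFrames indexed by OTU id with columns
``lineage`` (rank-prefixed, e.g. ``d__Bacteria;...;g__Prochlorococcus``),
``confidence`` ([0, 1]), ``group`` (analysis group) and ``marker``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fractions import DEFAULT_FRACTIONS, SizeFraction

SAMPLE_LEVELS = ("depth", "fraction", "marker")

#: Lineage keywords excluded from the picophytoplankton dataset.
DEFAULT_EXCLUDED_GROUPS = ("Archaea", "Fungi", "Embryophyta", "Metazoa")

#: Depth (m) of the deep chlorophyll maximum in the sampled column.
DCM_DEPTH_M = 113

_RANK_PREFIX = {
    "domain": "d__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
}


def make_sample_index(keys: list[tuple[float, str, str]]) -> pd.MultiIndex:
    """Build the (depth, fraction, marker) sample column index."""
    idx = pd.MultiIndex.from_tuples(keys, names=SAMPLE_LEVELS)
    if idx.duplicated().any():
        raise ValueError("sample keys must be unique")
    return idx


def validate_otu_table(table: pd.DataFrame) -> None:
    if (table.to_numpy() < 0).any():
        raise ValueError("OTU table contains negative counts")
    if tuple(table.columns.names) != SAMPLE_LEVELS:
        raise ValueError(
            f"OTU table columns must be a {SAMPLE_LEVELS} MultiIndex"
        )


@dataclass
class FilterLog:
    """Per-rule record of OTUs removed by :func:`filter_otus`."""

    low_abundance: list[str] = field(default_factory=list)
    low_confidence: list[str] = field(default_factory=list)
    excluded_lineage: list[str] = field(default_factory=list)
    unannotated: list[str] = field(default_factory=list)

    @property
    def removed(self) -> set[str]:
        return (
            set(self.low_abundance)
            | set(self.low_confidence)
            | set(self.excluded_lineage)
            | set(self.unannotated)
        )


def filter_otus(
    table: pd.DataFrame,
    tax: pd.DataFrame,
    min_total_fraction: float = 0.00005,
    min_confidence: float = 0.6,
    excluded_groups: tuple[str, ...] = DEFAULT_EXCLUDED_GROUPS,
) -> tuple[pd.DataFrame, FilterLog]:
    """Apply the three OTU retention rules and report what each removed.

    1. Abundance: an OTU whose summed reads across all samples of its
       marker are below ``min_total_fraction`` of that marker's grand
       total is dropped (0.005% by default).
    2. Annotation confidence below ``min_confidence`` (0.6) drops the OTU,
       as does a missing/empty annotation.
    3. Lineages matching any ``excluded_groups`` keyword (archaea, land
       plants, fungi, zooplankton by default) are dropped regardless of
       abundance.

    Returns the filtered table and a :class:`FilterLog`.  Reapplying the
    filter to its own output removes nothing further (the marker totals
    only shrink, so the abundance threshold shrinks with them).
    """
    if not 0 <= min_total_fraction <= 1 or not 0 <= min_confidence <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    log = FilterLog()
    if table.empty:
        warnings.warn("filter_otus received an empty OTU table", stacklevel=2)
        return table.copy(), log
    validate_otu_table(table)

    markers = table.columns.get_level_values("marker")
    marker_totals = {
        m: float(table.loc[:, markers == m].to_numpy().sum())
        for m in markers.unique()
    }

    for otu in table.index:
        row = table.loc[otu]
        # an OTU is kept if it clears the abundance bar in any marker
        # where it has reads (in practice each OTU belongs to one marker)
        per_marker = row.groupby(level="marker").sum()
        present = per_marker[per_marker > 0]
        if len(present) and all(
            present[m] < min_total_fraction * marker_totals[m] for m in present.index
        ):
            log.low_abundance.append(otu)

        if otu not in tax.index or not str(tax.loc[otu, "lineage"]).strip():
            log.unannotated.append(otu)
            continue
        if float(tax.loc[otu, "confidence"]) < min_confidence:
            log.low_confidence.append(otu)
        lineage = str(tax.loc[otu, "lineage"])
        if any(kw.lower() in lineage.lower() for kw in excluded_groups):
            log.excluded_lineage.append(otu)

    keep = [o for o in table.index if o not in log.removed]
    return table.loc[keep], log


def select_group_otus(tax: pd.DataFrame, group: str) -> pd.Index:
    """OTU ids belonging to an analysis group.

    ``group="picoeukaryote"`` selects every 18S-marker OTU not mapped to
    the ``excluded`` or ``background`` bins; any other label matches the
    taxonomy ``group`` column exactly (e.g. ``"Prochlorococcus"``,
    ``"Hemiselmis"``, ``"Prymnesiophyceae"``).
    """
    if group == "picoeukaryote":
        return tax.index[
            (tax["marker"] == "18S") & ~tax["group"].isin(["excluded", "background"])
        ]
    return tax.index[tax["group"] == group]


def _scoped(table: pd.DataFrame, depth: float | None) -> pd.DataFrame:
    if depth is None:
        return table
    depths = table.columns.get_level_values("depth")
    if depth not in depths:
        raise ValueError(f"depth {depth} m not present in table")
    return table.loc[:, depths == depth]


def _sample_weights(table: pd.DataFrame, normalize: str) -> pd.DataFrame:
    """Counts, optionally rescaled to per-sample relative abundance."""
    if normalize == "raw":
        return table.astype(float)
    if normalize == "library":
        sums = table.sum(axis=0)
        safe = sums.replace(0, np.nan)
        return table.div(safe, axis=1).fillna(0.0)
    raise ValueError(f"unknown normalization mode: {normalize!r}")


def fraction_proportions(
    filtered: pd.DataFrame,
    tax: pd.DataFrame,
    group: str,
    depth: float | None = None,
    fractions: tuple[SizeFraction, ...] = DEFAULT_FRACTIONS,
    normalize: str = "library",
) -> pd.Series:
    """Read proportions of a taxon group across the size fractions (N%).

    With ``normalize="library"`` (default) each sample's counts are first
    scaled to its library size, so arbitrary per-sample sequencing depth
    cannot masquerade as size structure; ``normalize="raw"`` pools raw
    reads, the convention behind the published per-fraction percentages.

    The result is indexed by fraction label, sums to 1, and carries the
    group's total read basis in ``.attrs["basis"]``.
    """
    otus = select_group_otus(tax, group)
    otus = otus.intersection(filtered.index)
    scoped = _scoped(filtered, depth)
    if len(otus) == 0:
        raise ValueError(f"group {group!r} absent after filtering")
    weights = _sample_weights(scoped, normalize)
    sub = weights.loc[otus]
    per_fraction = sub.T.groupby(level="fraction").sum().sum(axis=1)
    per_fraction = per_fraction.reindex([f.label for f in fractions], fill_value=0.0)
    total = float(per_fraction.sum())
    if total == 0:
        raise ValueError(f"group {group!r} has no reads in scope")
    props = per_fraction / total
    props.name = group
    props.attrs["basis"] = float(filtered.loc[otus].to_numpy().sum())
    return props


def estimate_diameter_sm(
    proportions: pd.Series | np.ndarray,
    fractions: tuple[SizeFraction, ...] = DEFAULT_FRACTIONS,
    tol: float = 1e-6,
) -> float:
    """Midpoint-weighted SM diameter (μm): Σ_f midpoint_f · N%_f.

    ``proportions`` must align with ``fractions`` (ascending) and sum to 1
    within ``tol``.
    """
    p = np.asarray(proportions, dtype=float)
    if p.shape != (len(fractions),):
        raise ValueError(
            f"expected {len(fractions)} proportions, got shape {p.shape}"
        )
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"proportions sum to {p.sum():.8f}, not 1")
    midpoints = np.array([f.midpoint for f in fractions])
    return float(midpoints @ p)


def vertical_profiles(
    filtered: pd.DataFrame,
    tax: pd.DataFrame,
    groups: list[str],
    normalize: str = "library",
) -> pd.DataFrame:
    """Per-group read totals by depth, summed over fractions.

    Rows are groups, columns depths (ascending).  The per-group argmax
    depth is stored in ``.attrs["argmax_depth"]``; the DCM depth, when
    sampled, is tagged in ``.attrs["dcm_depth"]``.
    """
    weights = _sample_weights(filtered, normalize)
    depths = sorted(set(filtered.columns.get_level_values("depth")))
    rows = {}
    for group in groups:
        otus = select_group_otus(tax, group).intersection(filtered.index)
        by_depth = weights.loc[otus].T.groupby(level="depth").sum().sum(axis=1)
        rows[group] = by_depth.reindex(depths, fill_value=0.0)
    out = pd.DataFrame(rows).T
    out.attrs["argmax_depth"] = {g: float(out.loc[g].idxmax()) for g in out.index}
    if DCM_DEPTH_M in depths:
        out.attrs["dcm_depth"] = DCM_DEPTH_M
    return out


def relative_abundance(
    filtered: pd.DataFrame,
    tax: pd.DataFrame,
    rank: str = "class",
    depth: float | None = None,
    marker: str | None = None,
    normalize: str = "library",
) -> pd.Series:
    """Composition at a taxonomic rank: proportions summing to 1 in scope."""
    prefix = _RANK_PREFIX.get(rank)
    if prefix is None:
        raise ValueError(f"unknown rank: {rank!r}")
    scoped = _scoped(filtered, depth)
    if marker is not None:
        markers = scoped.columns.get_level_values("marker")
        scoped = scoped.loc[:, markers == marker]
    weights = _sample_weights(scoped, normalize)

    def rank_label(otu: str) -> str:
        if otu not in tax.index:
            return "unannotated"
        for part in str(tax.loc[otu, "lineage"]).split(";"):
            if part.strip().startswith(prefix):
                return part.strip()[len(prefix):]
        return "unannotated"

    labels = pd.Series({o: rank_label(o) for o in weights.index})
    totals = weights.sum(axis=1).groupby(labels).sum()
    grand = float(totals.sum())
    if grand == 0:
        raise ValueError("no reads in scope")
    return (totals / grand).sort_values(ascending=False)
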