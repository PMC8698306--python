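"""Plain-text interchange for event tables, OTU counts, taxonomy and
environmental profiles.

Sample ids are flat strings ``<depth>m_<fraction>_<marker>`` (e.g.
``113m_0.2-0.6_18S``) in files and a (depth, fraction, marker)
MultiIndex in memory.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .sm import SAMPLE_LEVELS


def sample_id(depth: float, fraction: str, marker: str) -> str:
    return f"{depth:g}m_{fraction}_{marker}"


def parse_sample_id(sid: str) -> tuple[float, str, str]:
    depth_part, fraction, marker = sid.split("_")
    if not depth_part.endswith("m"):
        raise ValueError(f"malformed sample id: {sid!r}")
    return float(depth_part[:-1]), fraction, marker


def write_event_table(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_event_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_otu_table(table: pd.DataFrame, path: str | Path) -> None:
    flat = table.copy()
    flat.columns = [sample_id(*key) for key in table.columns]
    flat.index.name = "otu_id"
    flat.to_csv(path, sep="\t")


def read_otu_table(path: str | Path) -> pd.DataFrame:
    flat = pd.read_csv(path, sep="\t", index_col=0)
    keys = [parse_sample_id(c) for c in flat.columns]
    flat.columns = pd.MultiIndex.from_tuples(keys, names=SAMPLE_LEVELS)
    return flat


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    tax.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).fillna({"lineage": ""})


def write_env_profile(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path)


def read_env_profile(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
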