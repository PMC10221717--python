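"""CSV and config-file I/O.

Everything is plain UTF-8 CSV with a header: the droplet-level event
table (one row per droplet), the cluster-count table (one row per well)
and the per-well results table. Config files are YAML documents whose
keys mirror the config dataclass field names exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .errors import InputError
from .quant import TwoChannelCounts
from .sim import AmplitudeModel, AssayConfig, CellAssayConfig, VirusPrep

EVENT_COLUMNS = ["well_id", "droplet_index", "ch1_amplitude", "ch2_amplitude"]
CLUSTER_COLUMNS = ["well_id", "n_total", "n_pos_ch1", "n_pos_ch2", "n_double_pos"]


def write_event_table(events: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise InputError(f"event table lacks columns {missing}")
    events[EVENT_COLUMNS].to_csv(path, index=False)


def read_event_table(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise InputError(f"{path}: event table lacks columns {missing}")
    if len(events) == 0:
        raise InputError(f"{path}: empty event table")
    return events


def write_cluster_counts(
    wells: Iterable[tuple[str, TwoChannelCounts]], path: str | Path
) -> None:
    rows = [
        {
            "well_id": well_id,
            "n_total": c.n_total,
            "n_pos_ch1": c.n_pos_a,
            "n_pos_ch2": c.n_pos_b,
            "n_double_pos": c.n_double_pos,
        }
        for well_id, c in wells
    ]
    pd.DataFrame(rows, columns=CLUSTER_COLUMNS).to_csv(path, index=False)


def read_cluster_counts(path: str | Path) -> list[tuple[str, TwoChannelCounts]]:
    """Read per-well cluster counts; n_pos_ch1/2 include double positives."""
    table = pd.read_csv(path)
    missing = [c for c in CLUSTER_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"{path}: cluster-count table lacks columns {missing}")
    wells = []
    for row in table.itertuples(index=False):
        dp = row.n_double_pos
        counts = TwoChannelCounts(
            n_total=int(row.n_total),
            n_pos_a_only=row.n_pos_ch1 - dp,
            n_pos_b_only=row.n_pos_ch2 - dp,
            n_double_pos=dp,
            n_double_neg=int(row.n_total) - row.n_pos_ch1 - row.n_pos_ch2 + dp,
        )
        wells.append((str(row.well_id), counts))
    return wells


def load_config(path: str | Path) -> dict:
    """Load a YAML config into typed config objects.

    Recognised top-level keys: ``assay`` (AssayConfig fields), ``preps``
    (list of VirusPrep field mappings), ``cell`` (CellAssayConfig
    fields), ``amplitude`` (AmplitudeModel fields; tuples accepted as
    2-lists). Absent keys are simply absent from the returned dict.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    if "assay" in raw:
        out["assay"] = AssayConfig(**raw["assay"])
    if "preps" in raw:
        out["preps"] = [VirusPrep(**p) for p in raw["preps"]]
    if "cell" in raw:
        cell = dict(raw["cell"])
        if "occupancy_probs" in cell and cell["occupancy_probs"] is not None:
            cell["occupancy_probs"] = tuple(cell["occupancy_probs"])
        out["cell"] = CellAssayConfig(**cell)
    if "amplitude" in raw:
        amp = {
            k: tuple(v) if isinstance(v, (list, tuple)) else v
            for k, v in raw["amplitude"].items()
        }
        out["amplitude"] = AmplitudeModel(**amp)
    return out
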