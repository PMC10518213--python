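"""Reading and writing sweep datasets and expression matrices.

The native sweep format is a tab-separated samples table with one row
per sample (columns: sweep_id, cell_id, trial_index, sample_index,
value) plus a JSON sidecar carrying per-sweep metadata and the schema
version. The sidecar's ``sweeps`` list is indexed by ``sweep_id``;
cell_id/trial_index are duplicated in the table so it remains
inspectable on its own. Signals are written in their declared units
(pA for voltage clamp, mV otherwise).

Expression matrices are read/written as dense CSV (cells x genes, first
column the cell id) with a companion cluster-label CSV; MatrixMarket
input is also accepted for the values.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io

from .datamodel import (
    ExpressionMatrix,
    Modality,
    SchemaError,
    SweepRecord,
    sweep_sort_key,
)

SCHEMA_VERSION = 1

_TABLE_COLUMNS = ["sweep_id", "cell_id", "trial_index", "sample_index", "value"]
_META_FIELDS = (
    "cell_id",
    "modality",
    "sampling_rate",
    "holding_potential",
    "ljp_corrected",
    "condition",
    "trial_index",
    "stimulus_id",
    "n_samples",
)


def _sidecar_path(table_path: Path) -> Path:
    return table_path.with_suffix(table_path.suffix + ".json")


def save_dataset(sweeps: Sequence[SweepRecord], path: Union[str, Path]) -> None:
    """Write sweeps as a TSV samples table plus JSON metadata sidecar."""
    path = Path(path)
    ordered = sorted(sweeps, key=sweep_sort_key)
    meta = {"schema_version": SCHEMA_VERSION, "units": "pA|mV", "sweeps": []}
    frames: List[pd.DataFrame] = []
    for sweep_id, sw in enumerate(ordered):
        meta["sweeps"].append(
            {
                "cell_id": sw.cell_id,
                "modality": sw.modality.value,
                "sampling_rate": sw.sampling_rate,
                "holding_potential": sw.holding_potential,
                "ljp_corrected": sw.ljp_corrected,
                "condition": sw.condition,
                "trial_index": sw.trial_index,
                "stimulus_id": sw.stimulus_id,
                "n_samples": sw.n_samples,
            }
        )
        frames.append(
            pd.DataFrame(
                {
                    "sweep_id": sweep_id,
                    "cell_id": sw.cell_id,
                    "trial_index": sw.trial_index,
                    "sample_index": np.arange(sw.n_samples),
                    "value": sw.signal,
                }
            )
        )
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=_TABLE_COLUMNS)
    # %.10g keeps round-trips exact to ~1e-9 relative, far below any
    # physiological precision while staying diff-able.
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def load_dataset(path: Union[str, Path], format: str = "sweep_table") -> List[SweepRecord]:
    """Load all sweeps from a dataset, ordered by (cell_id, condition, trial_index)."""
    if format != "sweep_table":
        raise ValueError(
            f"unsupported format {format!r}; only 'sweep_table' is available"
        )
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SchemaError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema_version {meta.get('schema_version')!r}"
        )
    table = pd.read_csv(path, sep="\t")
    missing = set(_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"samples table missing columns: {sorted(missing)}")

    groups = dict(iter(table.groupby("sweep_id"))) if len(table) else {}
    sweeps: List[SweepRecord] = []
    for sweep_id, entry in enumerate(meta.get("sweeps", [])):
        for key in _META_FIELDS:
            if key not in entry:
                raise SchemaError(f"sweep {sweep_id}: sidecar missing {key!r}")
        if entry["modality"] == Modality.VOLTAGE_CLAMP.value and entry[
            "holding_potential"
        ] is None:
            raise SchemaError(
                f"sweep {sweep_id}: voltage_clamp sweep lacks holding_potential"
            )
        if sweep_id not in groups:
            raise SchemaError(f"sweep {sweep_id}: no samples in table")
        rows = groups[sweep_id].sort_values("sample_index")
        signal = rows["value"].to_numpy(dtype=float)
        if signal.size != entry["n_samples"]:
            raise SchemaError(
                f"sweep {sweep_id}: expected {entry['n_samples']} samples, "
                f"found {signal.size}"
            )
        sweeps.append(
            SweepRecord(
                cell_id=entry["cell_id"],
                modality=Modality(entry["modality"]),
                sampling_rate=entry["sampling_rate"],
                signal=signal,
                holding_potential=entry["holding_potential"],
                ljp_corrected=bool(entry["ljp_corrected"]),
                condition=entry["condition"],
                trial_index=int(entry["trial_index"]),
                stimulus_id=entry["stimulus_id"],
            )
        )
    sweeps.sort(key=sweep_sort_key)
    return sweeps


def save_expression(
    matrix: ExpressionMatrix, values_path: Union[str, Path], labels_path: Union[str, Path]
) -> None:
    """Write an expression matrix as dense CSV plus a cluster-label CSV."""
    df = pd.DataFrame(
        matrix.values,
        index=[f"cell_{i}" for i in range(matrix.n_cells)],
        columns=list(matrix.gene_ids),
    )
    df.index.name = "cell"
    df.to_csv(values_path)
    pd.DataFrame(
        {"cell": df.index, "cluster": list(matrix.cluster_labels)}
    ).to_csv(labels_path, index=False)


def load_expression(
    values_path: Union[str, Path], labels_path: Union[str, Path]
) -> ExpressionMatrix:
    """Load an expression matrix from dense CSV or MatrixMarket values.

    MatrixMarket input (``.mtx``) must be accompanied by a labels CSV
    whose optional ``gene`` column supplies gene ids; dense CSV carries
    gene ids in its header.
    """
    values_path = Path(values_path)
    labels = pd.read_csv(labels_path)
    if "cluster" not in labels.columns:
        raise SchemaError("cluster-label CSV requires a 'cluster' column")
    if values_path.suffix == ".mtx":
        values = np.asarray(scipy.io.mmread(values_path).todense(), dtype=float)
        if "gene" in labels.columns:
            gene_ids = list(pd.unique(labels["gene"].dropna()))
        else:
            gene_ids = [f"gene_{j}" for j in range(values.shape[1])]
    else:
        df = pd.read_csv(values_path, index_col=0)
        values = df.to_numpy(dtype=float)
        gene_ids = list(df.columns)
    return ExpressionMatrix(
        values=values,
        cluster_labels=list(labels["cluster"]),
        gene_ids=gene_ids,
    )
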