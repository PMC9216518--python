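"""Tab-delimited I/O for matrices, annotations and result tables.

All tabular outputs carry their provenance (thresholds, seeds, scale tags)
as ``# key\tvalue`` comment lines above the header so that a result file is
self-describing.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import AbundanceMatrix, DataError, SampleAnnotation


def write_table(df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None,
                index_label: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}\t{value}\n")
        df.to_csv(fh, sep="\t", index=True, index_label=index_label)


def read_table(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_metadata(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("\t")
            meta[key] = value
    return meta


def write_matrix(m: AbundanceMatrix, path: str | Path) -> None:
    write_table(m.data, path, metadata={"scale_tag": m.scale_tag}, index_label="feature_id")


def read_matrix(path: str | Path, scale_tag: str | None = None) -> AbundanceMatrix:
    """Read a features × samples matrix.

    The scale tag is taken from the file's metadata header when present;
    an explicit ``scale_tag`` argument overrides it.
    """
    df = read_table(path)
    if scale_tag is None:
        scale_tag = read_metadata(path).get("scale_tag", "raw")
    return AbundanceMatrix(df, scale_tag=scale_tag)


def write_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    write_table(ann.table, path, index_label="sample_id")


def read_annotation(path: str | Path) -> SampleAnnotation:
    return SampleAnnotation(read_table(path))


def write_json(obj: object, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path: str | Path) -> object:
    with open(path) as fh:
        return json.load(fh)
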