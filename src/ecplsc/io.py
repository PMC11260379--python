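"""Plain-text readers and writers for the pipeline's file formats.

Time series are TSV matrices (rows = regions, columns = timepoints, no
header), one file per subject named ``<subject_id>_ts.tsv``. The atlas is a
TSV with columns index, region_name, network_name. FC matrices are TSV;
feature matrices and score tables are CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import FCMatrix, RegionTimeSeries
from .errors import ValidationError


def read_atlas(path: str | Path) -> pd.DataFrame:
    atlas = pd.read_csv(path, sep="\t")
    required = {"index", "region_name", "network_name"}
    missing = required - set(atlas.columns)
    if missing:
        raise ValidationError(f"atlas file lacks columns: {sorted(missing)}")
    return atlas.sort_values("index").reset_index(drop=True)


def read_timeseries_dir(
    ts_dir: str | Path, tr: float, region_ids: list | None = None
) -> list[RegionTimeSeries]:
    """Load every ``*_ts.tsv`` in a directory, sorted by subject id."""
    paths = sorted(Path(ts_dir).glob("*_ts.tsv"))
    if not paths:
        raise ValidationError(f"no *_ts.tsv files found in {ts_dir}")
    out = []
    for p in paths:
        data = np.loadtxt(p, delimiter="\t")
        out.append(
            RegionTimeSeries(
                data=np.atleast_2d(data),
                tr=tr,
                region_ids=list(region_ids) if region_ids else [],
                subject_id=p.name[: -len("_ts.tsv")],
            )
        )
    return out


def write_fc(fc: FCMatrix, path: str | Path) -> None:
    np.savetxt(path, fc.values, delimiter="\t")


def read_fc(path: str | Path, region_ids: list | None = None) -> FCMatrix:
    values = np.loadtxt(path, delimiter="\t")
    return FCMatrix(values=values, region_ids=list(region_ids) if region_ids else [])


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_feature_matrix(X: pd.DataFrame, path: str | Path) -> None:
    X.to_csv(path, index_label="subject_id")
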