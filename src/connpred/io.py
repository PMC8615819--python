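"""Delimited-text readers and writers binding the pipeline stages together.

Canonical on-disk formats (all diffable plain text):

* time series — header-free TSV, T rows x R columns, one file per subject;
* cohort manifest — CSV with header ``subject_id,timeseries_path,score``;
* atlas labels — TSV with header ``index\\tname\\tabbreviation``;
* connectivity matrices — TSV with a one-line ``#`` header naming the kind
  and region labels;
* feature matrices — TSV plus an index-map JSON sidecar;
* results — JSON.

``.gz`` suffixed inputs are accepted transparently.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, FeatureVector, Kind, RegionTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "CohortManifest",
    "read_timeseries",
    "write_timeseries",
    "read_manifest",
    "write_manifest",
    "read_atlas_labels",
    "aal90_labels",
    "read_connectivity",
    "write_connectivity",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_config",
    "write_cohort",
]


@dataclass
class CohortManifest:
    table: pd.DataFrame  # columns: subject_id, timeseries_path, score

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy(dtype=float)

    def paths(self) -> list[Path]:
        return [Path(p) for p in self.table["timeseries_path"]]


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_timeseries(path, subject_id: str | None = None) -> RegionTimeSeries:
    """Header-free TSV of T rows x R columns; errors on ragged/non-numeric rows."""
    path = Path(path)
    try:
        with _open_text(path) as fh:
            df = pd.read_csv(fh, sep="\t", header=None, dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed time-series file {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"time-series file {path} has missing or ragged cells")
    sid = subject_id if subject_id is not None else path.name.split(".")[0]
    return RegionTimeSeries(df.to_numpy(), subject_id=sid)


def write_timeseries(ts: RegionTimeSeries, path) -> None:
    np.savetxt(path, ts.values, delimiter="\t", fmt="%.10g")


def read_manifest(path, check_paths: bool = True) -> CohortManifest:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "timeseries_path", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest {path} must have columns {sorted(required)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject id {dup!r} in manifest")
    try:
        scores = df["score"].astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric score in manifest: {exc}") from exc
    out_of_range = (scores < 0) | (scores > 100)
    if out_of_range.any():
        logger.warning(
            "manifest: %d score(s) outside [0, 100]; values retained",
            int(out_of_range.sum()),
        )
    df = df.assign(score=scores)
    # relative paths resolve against the manifest's directory
    df["timeseries_path"] = [
        str(p if Path(p).is_absolute() else path.parent / p)
        for p in df["timeseries_path"]
    ]
    if check_paths:
        for sid, p in zip(df["subject_id"], df["timeseries_path"]):
            if not Path(p).exists():
                raise FileNotFoundError(f"time series for subject {sid!r} not found: {p}")
    return CohortManifest(df[["subject_id", "timeseries_path", "score"]])


def write_manifest(manifest: CohortManifest, path) -> None:
    manifest.table.to_csv(path, index=False)


def read_atlas_labels(path, expected_regions: int | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"index", "name", "abbreviation"}
    if not required.issubset(df.columns):
        raise ValueError(f"atlas table must have columns {sorted(required)}")
    if expected_regions is not None and len(df) != expected_regions:
        raise ValueError(
            f"atlas table has {len(df)} rows but {expected_regions} regions are configured"
        )
    return df.reset_index(drop=True)


def aal90_labels() -> pd.DataFrame:
    """The 90-region AAL cerebrum parcellation (cerebellum excluded)."""
    with resources.files("connpred.data").joinpath("aal90_labels.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def write_connectivity(matrix: ConnectivityMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#kind={matrix.kind.value}\tlabels={','.join(matrix.region_labels)}\n")
        np.savetxt(fh, matrix.values, delimiter="\t", fmt="%.17g")


def read_connectivity(path) -> ConnectivityMatrix:
    with _open_text(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#kind="):
            raise ValueError(f"{path}: missing connectivity header")
        fields = dict(item.split("=", 1) for item in header[1:].split("\t"))
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    labels = fields.get("labels", "").split(",")
    return ConnectivityMatrix(values, Kind(fields["kind"]), labels)


def write_feature_matrix(X: np.ndarray, index_map, path) -> None:
    path = Path(path)
    np.savetxt(path, X, delimiter="\t", fmt="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"index_map": [list(t) for t in index_map]}, fh)


def read_feature_matrix(path):
    path = Path(path)
    X = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar) as fh:
        index_map = [tuple(t) for t in json.load(fh)["index_map"]]
    return X, index_map


def read_config(path) -> dict[str, str]:
    """Flat ``key = value`` text configuration; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def write_cohort(cohort, out_dir) -> Path:
    """Write a synthetic cohort: per-subject TSVs, manifest, truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts, score in zip(cohort.subjects, cohort.scores):
        fname = f"{ts.subject_id}.tsv"
        write_timeseries(ts, out_dir / fname)
        rows.append({"subject_id": ts.subject_id, "timeseries_path": fname,
                     "score": float(score)})
    manifest = CohortManifest(pd.DataFrame(rows))
    write_manifest(manifest, out_dir / "manifest.csv")
    t = cohort.truth
    truth = {
        "planted_edges": [[e.i, e.j, e.pool] for e in t.planted_edges],
        "weights": t.weights.tolist(),
        "noise_sd": t.noise_sd,
        "score_offset": t.score_offset,
        "score_scale": t.score_scale,
        "pattern_seed": t.pattern_seed,
        "master_seed": cohort.master_seed,
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return out_dir / "manifest.csv"
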