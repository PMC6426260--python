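"""File I/O: NIfTI / HDF5 time series, event tables, result tables, configs.

Formats
-------
* time series: 4-D NIfTI plus a JSON sidecar ``{"run_lengths": [...],
  "tr_seconds": x}``, or an HDF5 file with datasets ``signal`` (time x
  voxels), ``run_index`` and attribute ``tr_seconds``;
* event tables: tab-delimited text with columns ``run``, ``onset_seconds``,
  ``duration_seconds``, ``stimulus_id`` (onsets relative to run start);
* response estimates: HDF5 with ``beta_hat``, ``var_diag``, optionally
  ``beta_hat_by_run``;
* result tables: tab-delimited with a one-line header;
* configs and provenance: JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StimulusDesign, design_from_events
from .glm import ResponseEstimate, TimeSeriesDataset

__all__ = [
    "RunConfig",
    "VolumeGrid",
    "load_timeseries",
    "read_events",
    "design_from_event_file",
    "save_response_h5",
    "load_response_h5",
    "save_map_nifti",
    "write_table",
    "read_table",
    "write_provenance",
]


@dataclass
class RunConfig:
    """Resolved command configuration; serialises losslessly to JSON."""

    command: str
    inputs: dict = field(default_factory=dict)
    output_dir: str = "."
    options: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        text = source if str(source).lstrip().startswith("{") else \
            Path(source).read_text()
        return cls(**json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class VolumeGrid:
    """Spatial geometry of a NIfTI input, for writing aligned maps."""

    shape: tuple
    affine: np.ndarray


def _run_index_from_lengths(run_lengths) -> np.ndarray:
    return np.concatenate(
        [np.full(int(t), r) for r, t in enumerate(run_lengths)]
    )


def load_timeseries(path, runs_json=None):
    """Load a 4-D NIfTI (with run sidecar) or HDF5 time-series file.

    Returns ``(TimeSeriesDataset, VolumeGrid | None)``; NIfTI volumes are
    flattened to (time, voxels) in C order.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            signal = fh["signal"][()]
            run_index = fh["run_index"][()]
            tr = float(fh.attrs.get("tr_seconds", 2.6))
        return TimeSeriesDataset(signal, run_index, tr), None
    if runs_json is None:
        raise FileNotFoundError(
            f"NIfTI input {path} needs a run sidecar JSON "
            '({"run_lengths": [...], "tr_seconds": x}); pass runs_json'
        )
    runs_json = Path(runs_json)
    if not runs_json.exists():
        raise FileNotFoundError(
            f"expected run sidecar file {runs_json} next to {path}"
        )
    import nibabel as nib

    sidecar = json.loads(runs_json.read_text())
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError("time-series NIfTI must be 4-D")
    t = data.shape[3]
    signal = data.reshape(-1, t).T
    run_lengths = sidecar["run_lengths"]
    if int(np.sum(run_lengths)) != t:
        raise ValueError(
            f"run_lengths sum to {int(np.sum(run_lengths))} but the image "
            f"has {t} volumes"
        )
    ds = TimeSeriesDataset(
        signal,
        _run_index_from_lengths(run_lengths),
        float(sidecar.get("tr_seconds", 2.6)),
    )
    return ds, VolumeGrid(shape=data.shape[:3], affine=img.affine)


def read_events(path) -> pd.DataFrame:
    """Read a tab-delimited event table (run, onset_seconds, duration_seconds,
    stimulus_id)."""
    events = pd.read_csv(path, sep="\t")
    required = {"run", "onset_seconds", "stimulus_id"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table {path} is missing columns {sorted(missing)}")
    return events


def design_from_event_file(path, run_lengths, tr_seconds) -> StimulusDesign:
    """Event table -> HRF-convolved design; onsets are binned to the nearest TR.

    ``stimulus_id`` values are mapped to columns in sorted order.
    """
    events = read_events(path)
    ids = np.sort(events["stimulus_id"].unique())
    id_map = {s: i for i, s in enumerate(ids)}
    table = pd.DataFrame({
        "run": events["run"].astype(int),
        "onset_tr": np.rint(events["onset_seconds"] / tr_seconds).astype(int),
        "stimulus": events["stimulus_id"].map(id_map),
    })
    lengths = {r: int(t) for r, t in enumerate(run_lengths)}
    design = design_from_events(table, lengths, tr_seconds, n_stimuli=len(ids))
    design.stimulus_ids = ids  # type: ignore[attr-defined]
    return design


def save_response_h5(est: ResponseEstimate, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("beta_hat", data=est.beta_hat)
        fh.create_dataset("var_diag", data=est.var_diag)
        if est.beta_hat_by_run is not None:
            fh.create_dataset("beta_hat_by_run", data=est.beta_hat_by_run)
        fh.attrs["estimator_kind"] = est.estimator_kind
        fh.attrs["combine"] = est.combine


def load_response_h5(path) -> ResponseEstimate:
    import h5py

    with h5py.File(path, "r") as fh:
        by_run = fh["beta_hat_by_run"][()] if "beta_hat_by_run" in fh else None
        return ResponseEstimate(
            beta_hat=fh["beta_hat"][()],
            var_diag=fh["var_diag"][()],
            estimator_kind=str(fh.attrs.get("estimator_kind", "identity")),
            beta_hat_by_run=by_run,
            combine=str(fh.attrs.get("combine", "whole_series")),
        )


def save_map_nifti(values, grid: VolumeGrid, path) -> None:
    """Write a per-voxel map as a 3-D NIfTI aligned to the input grid."""
    import nibabel as nib

    vol = np.asarray(values, dtype=float).reshape(grid.shape)
    nib.Nifti1Image(vol, grid.affine).to_filename(str(path))


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_provenance(config: RunConfig, path) -> None:
    from . import __version__

    record = {
        "config": json.loads(config.to_json()),
        "config_sha256": config.digest(),
        "package_version": __version__,
        "seed": config.seed,
    }
    Path(path).write_text(json.dumps(record, indent=2) + "\n")
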