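"""CSV/JSON readers and writers plus seeded run manifests."""
from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_dynamics import DIVISION_COLUMNS, TRACK_COLUMNS, TrackDataset
from .errors import DataError
from .stack_synth import MorphometrySample
from .tmm import Spectrum

SPECTRUM_HEADER = ["wavelength_nm", "reflectance"]


def write_spectrum_csv(spectrum: Spectrum, path: str | Path, sidecar: bool = True) -> Path:
    """Write a spectrum as CSV at full float precision.

    With ``sidecar=True`` the metadata (preset, seed, n_runs, angle,
    convention, ...) lands in ``<path>.json`` next to the CSV.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SPECTRUM_HEADER)
        for wl, r in zip(spectrum.wavelengths, spectrum.reflectance):
            w.writerow([repr(float(wl)), repr(float(r))])
    if sidecar and spectrum.metadata:
        Path(str(path) + ".json").write_text(json.dumps(spectrum.metadata, indent=2))
    return path


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Read a spectrum CSV; malformed rows raise with their line number."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DataError(f"{path}: empty file") from None
        if [h.strip() for h in header] != SPECTRUM_HEADER:
            raise DataError(
                f"{path}: line 1: expected header {','.join(SPECTRUM_HEADER)}"
            )
        wl: list[float] = []
        refl: list[float] = []
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise DataError(f"{path}: line {i}: expected 2 columns, got {len(row)}")
            try:
                wl.append(float(row[0]))
                refl.append(float(row[1]))
            except ValueError as exc:
                raise DataError(f"{path}: line {i}: {exc}") from None
    wl_arr = np.asarray(wl)
    if wl_arr.size > 1 and not (np.diff(wl_arr) > 0).all():
        raise DataError(f"{path}: wavelengths must be strictly ascending")
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Spectrum(wl_arr, np.asarray(refl), meta)


def write_morphometry_csv(sample: MorphometrySample, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "length_um": sample.lengths,
        "width_um": sample.widths,
        "aspect_ratio": sample.aspect_ratios,
        "crystallotype": sample.crystallotype,
    }).to_csv(path, index=False)
    return path


def read_morphometry_csv(path: str | Path) -> MorphometrySample:
    df = pd.read_csv(path)
    needed = {"length_um", "width_um", "aspect_ratio", "crystallotype"}
    missing = needed - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    label = df["crystallotype"].iloc[0] if len(df) else "unspecified"
    return MorphometrySample(
        df["length_um"].to_numpy(float),
        df["width_um"].to_numpy(float),
        df["aspect_ratio"].to_numpy(float),
        str(label),
    )


def write_tracks_csv(
    dataset: TrackDataset, tracks_path: str | Path, divisions_path: str | Path
) -> tuple[Path, Path]:
    tracks_path, divisions_path = Path(tracks_path), Path(divisions_path)
    dataset.tracks[TRACK_COLUMNS].to_csv(tracks_path, index=False)
    dataset.divisions[DIVISION_COLUMNS].to_csv(divisions_path, index=False)
    return tracks_path, divisions_path


def read_tracks_csv(
    tracks_path: str | Path, divisions_path: str | Path | None = None
) -> TrackDataset:
    tracks = pd.read_csv(tracks_path)
    missing = set(TRACK_COLUMNS) - set(tracks.columns)
    if missing:
        raise DataError(f"{tracks_path}: missing columns {sorted(missing)}")
    if divisions_path is not None and Path(divisions_path).exists():
        divisions = pd.read_csv(divisions_path)
    else:
        divisions = pd.DataFrame(columns=DIVISION_COLUMNS)
    return TrackDataset(tracks, divisions)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted by every CLI/pipeline run."""

    command: str
    seed: int
    config: dict
    package_version: str = ""
    started_utc: str = ""
    finished_utc: str = ""
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def start(self) -> "RunManifest":
        self.started_utc = datetime.now(timezone.utc).isoformat()
        return self

    def record_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = sha256_of(path)

    def finish(self, path: str | Path) -> Path:
        from . import __version__

        self.package_version = self.package_version or __version__
        self.finished_utc = datetime.now(timezone.utc).isoformat()
        out = Path(path)
        out.write_text(json.dumps(asdict(self), indent=2))
        return out
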