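"""File formats: Weber CSV, manifest JSON, distribution tables, fit-result JSON.

Weber CSV holds one experiment per file with columns ``frequency_hz``,
``phase_deg``, ``mod_ratio`` and optional ``phase_sd_deg``, ``mod_sd``;
angles are degrees.  A manifest JSON maps files to their condition,
acceptor, ionic strength, replicate and labeled-sample ids, and carries
global analysis settings.  Spreadsheet source data is supported through a
converter to Weber CSV so the numeric core stays format-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import DistributionTable
from .fdmodel import FDDataset

__all__ = [
    "ManifestEntry",
    "Manifest",
    "read_weber_csv",
    "write_weber_csv",
    "read_manifest",
    "write_manifest",
    "load_datasets",
    "read_distribution_table",
    "convert_spreadsheet",
    "save_fit_result",
]

REQUIRED_COLUMNS = ("frequency_hz", "phase_deg", "mod_ratio")
OPTIONAL_COLUMNS = ("phase_sd_deg", "mod_sd")


def read_weber_csv(path: str | Path, **metadata) -> FDDataset:
    """Read one experiment's Weber CSV; metadata fields come from the caller.

    Raises a descriptive error (with row number) for missing columns,
    non-monotone frequencies, or out-of-range phase/modulation values.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    freqs = df["frequency_hz"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(freqs) <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: frequencies must be strictly increasing (data row {bad[0] + 2})"
        )
    mod = df["mod_ratio"].to_numpy(dtype=float)
    out_of_range = np.flatnonzero((mod <= 0) | (mod > 1))
    if out_of_range.size:
        raise ValueError(
            f"{path}: mod_ratio outside (0, 1] (data row {out_of_range[0] + 2})"
        )
    phase = df["phase_deg"].to_numpy(dtype=float)
    out_of_range = np.flatnonzero((phase <= -90) | (phase >= 180))
    if out_of_range.size:
        raise ValueError(
            f"{path}: phase_deg outside (-90, 180) (data row {out_of_range[0] + 2})"
        )
    kwargs = dict(metadata)
    if "phase_sd_deg" in df.columns:
        kwargs["phase_sd"] = df["phase_sd_deg"].to_numpy(dtype=float)
    if "mod_sd" in df.columns:
        kwargs["mod_sd"] = df["mod_sd"].to_numpy(dtype=float)
    return FDDataset(frequencies=freqs, phase_deg=phase, mod_ratio=mod, **kwargs)


def write_weber_csv(dataset: FDDataset, path: str | Path) -> None:
    """Write a Weber CSV; lossless round trip with :func:`read_weber_csv`."""
    cols = {
        "frequency_hz": dataset.frequencies,
        "phase_deg": dataset.phase_deg,
        "mod_ratio": dataset.mod_ratio,
    }
    if dataset.phase_sd is not None:
        cols["phase_sd_deg"] = dataset.phase_sd
    if dataset.mod_sd is not None:
        cols["mod_sd"] = dataset.mod_sd
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


@dataclass
class ManifestEntry:
    """One data file and its experimental context."""

    file: str
    condition: str
    acceptor: str
    ionic: str = "500"
    replicate_id: str = ""
    sample_id: str = ""
    buffer: str = ""


@dataclass
class Manifest:
    """Collection of Weber files plus global analysis settings."""

    entries: list[ManifestEntry]
    settings: dict = field(default_factory=dict)
    root: Path = Path(".")

    def __post_init__(self) -> None:
        self.settings.setdefault("temperature_K", 298.0)
        self.settings.setdefault("resting_floor", 0.01)
        self.settings.setdefault("sigma_phase_deg", 0.2)
        self.settings.setdefault("sigma_mod", 0.004)


def read_manifest(path: str | Path) -> Manifest:
    """Read a manifest JSON and validate that referenced files exist."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    entries = [ManifestEntry(**e) for e in raw["entries"]]
    root = path.parent
    for e in entries:
        if not (root / e.file).exists():
            raise FileNotFoundError(f"manifest references missing file {e.file!r}")
        if not e.sample_id:
            e.sample_id = e.replicate_id
    return Manifest(entries=entries, settings=raw.get("settings", {}), root=root)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    payload = {
        "entries": [vars(e) for e in manifest.entries],
        "settings": manifest.settings,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_datasets(manifest: Manifest) -> list[FDDataset]:
    """Load every dataset referenced by a manifest."""
    out = []
    for e in manifest.entries:
        out.append(
            read_weber_csv(
                manifest.root / e.file,
                condition=e.condition,
                acceptor=e.acceptor,
                ionic=e.ionic,
                replicate_id=e.replicate_id,
                sample_id=e.sample_id or e.replicate_id,
            )
        )
    return out


def read_distribution_table(path: str | Path) -> DistributionTable:
    """Read a two-column (distance Å, density) table for overlay comparison.

    Accepts comma-, tab- or whitespace-separated numeric text (the format
    rotamer-modeling tools export).  The density is renormalized to unit
    area; it is never used as a fit model.
    """
    path = Path(path)
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    except (pd.errors.EmptyDataError, csv.Error):
        raise ValueError(f"{path}: empty or unparseable table") from None
    # tolerate a header line of column names
    if not np.issubdtype(np.asarray(df.iloc[0]).dtype, np.number):
        df = df.iloc[1:]
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise ValueError(f"{path}: expected two numeric columns")
    r = df.iloc[:, 0].to_numpy(dtype=float)
    d = df.iloc[:, 1].to_numpy(dtype=float)
    return DistributionTable(r=r, density=d)


_SPREADSHEET_ALIASES = {
    "frequency_hz": ("frequency_hz", "frequency", "freq", "frequency (hz)", "freq_hz"),
    "phase_deg": ("phase_deg", "phase", "phase delay", "phase (deg)", "phase_delay_deg"),
    "mod_ratio": ("mod_ratio", "modulation", "modulation ratio", "mod", "m"),
}


def convert_spreadsheet(
    xlsx_path: str | Path,
    out_csv: str | Path,
    sheet: str | int = 0,
    frequency_unit: float = 1.0,
) -> Path:
    """Convert one sheet of a source-data spreadsheet to a Weber CSV.

    Columns are matched case-insensitively against common aliases
    (frequency/phase/modulation); ``frequency_unit`` scales the frequency
    column to Hz (e.g. 1e6 if the sheet is in MHz).
    """
    df = pd.read_excel(xlsx_path, sheet_name=sheet)
    lowered = {str(c).strip().lower(): c for c in df.columns}
    resolved = {}
    for target, aliases in _SPREADSHEET_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                resolved[target] = lowered[alias]
                break
        else:
            raise ValueError(
                f"{xlsx_path}: could not find a column for {target!r}; "
                f"columns present: {list(df.columns)}"
            )
    out = pd.DataFrame(
        {
            "frequency_hz": df[resolved["frequency_hz"]].astype(float) * frequency_unit,
            "phase_deg": df[resolved["phase_deg"]].astype(float),
            "mod_ratio": df[resolved["mod_ratio"]].astype(float),
        }
    ).dropna()
    out = out.sort_values("frequency_hz")
    out_csv = Path(out_csv)
    out.to_csv(out_csv, index=False)
    return out_csv


def save_fit_result(result, path: str | Path, extra: dict | None = None) -> None:
    """Write a FitResult (plus optional run metadata) as JSON."""
    payload = result.to_dict()
    if extra:
        payload["run"] = extra
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
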