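"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* EEG: EDF (the clinical standard exported by the recorder) read through
  :mod:`mne`; tab-separated text (TSV) for everything else.  A minimal EDF
  *writer* is implemented here because only an EDF reader is available as a
  library dependency.
* Parcellation: TSV table with one row per cortical region of the
  Desikan--Killiany atlas (68 regions, 34 per hemisphere).
* Results: per-region node metrics as TSV, diagnostic reports as JSON.

Indexing convention: region and vertex indices are **1-based in files** and
**0-based in memory**.  Conversion happens exactly once, at the read/write
boundary in this module.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecording",
    "ParcellationTable",
    "ClinicalRecord",
    "read_eeg",
    "write_eeg",
    "read_parcellation",
    "default_parcellation",
    "read_clinical_records",
    "write_results",
    "read_results_metrics",
    "read_results_report",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """Multichannel scalp EEG.

    Parameters
    ----------
    samples
        ``(n_channels, n_times)`` array in microvolts.
    rate
        Sampling rate in samples/second.
    channel_names
        Ordered 10--20 electrode labels, unique.
    onset_marker
        Sample index of electrographic seizure onset, or ``None``.
    """

    samples: np.ndarray
    rate: float
    channel_names: list[str]
    onset_marker: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} signal rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_times / self.rate


@dataclass
class ParcellationTable:
    """Desikan--Killiany style cortical parcellation (68 regions).

    ``vertex_ids`` are 0-based source-row indices; files store them 1-based.
    """

    region_ids: list[int]
    region_names: list[str]
    hemispheres: list[str]
    vertex_ids: list[list[int]]

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        if n != 68:
            raise ValueError(f"parcellation must contain exactly 68 regions, got {n}")
        if not (len(self.region_names) == len(self.hemispheres) == len(self.vertex_ids) == n):
            raise ValueError("parcellation columns have inconsistent lengths")
        if sorted(self.region_ids) != list(range(1, 69)):
            raise ValueError("region_ids must be exactly 1..68")
        for h in self.hemispheres:
            if h not in ("left", "right"):
                raise ValueError(f"hemisphere must be 'left' or 'right', got {h!r}")
        seen: set[int] = set()
        for rid, verts in zip(self.region_ids, self.vertex_ids):
            if len(verts) == 0:
                raise ValueError(f"region {rid} has an empty vertex set")
            overlap = seen.intersection(verts)
            if overlap:
                raise ValueError(
                    f"vertex sets overlap: vertex {min(overlap)} assigned twice"
                )
            seen.update(verts)

    @property
    def n_regions(self) -> int:
        return 68


@dataclass
class ClinicalRecord:
    """Per-patient surgical reference standard."""

    patient_id: str
    resected_regions: set[int]
    engel_class: str

    _VALID_ENGEL = ("I", "II", "III", "IV")

    def __post_init__(self) -> None:
        self.resected_regions = set(int(r) for r in self.resected_regions)
        if not all(1 <= r <= 68 for r in self.resected_regions):
            raise ValueError("resected_regions must be region ids in 1..68")
        if self.engel_class not in self._VALID_ENGEL:
            raise ValueError(
                f"engel_class must be one of {self._VALID_ENGEL}, got {self.engel_class!r}"
            )

    @property
    def favorable(self) -> bool:
        """Engel class I (seizure freedom) counts as a favorable outcome."""
        return self.engel_class == "I"


# ---------------------------------------------------------------------------
# EEG: TSV dialect
# ---------------------------------------------------------------------------

def _write_eeg_tsv(rec: EEGRecording, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# rate={rec.rate!r}")
        if rec.onset_marker is not None:
            fh.write(f"\tonset={rec.onset_marker}")
        fh.write("\n")
        fh.write("\t".join(rec.channel_names) + "\n")
        np.savetxt(fh, rec.samples.T, fmt="%.17g", delimiter="\t")


def _read_eeg_tsv(path: Path, rate: float | None) -> EEGRecording:
    onset = None
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                key, _, val = tok.partition("=")
                if key == "rate":
                    rate = float(val)
                elif key == "onset":
                    onset = int(val)
            header = fh.readline()
        else:
            header = first
        names = header.rstrip("\r\n").split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if rate is None:
        raise ValueError(
            "TSV file declares no sampling rate; pass rate= explicitly"
        )
    if len(set(names)) != len(names):
        raise ValueError("duplicate channel names in TSV header")
    return EEGRecording(samples=data.T, rate=rate, channel_names=names,
                        onset_marker=onset)


# ---------------------------------------------------------------------------
# EEG: EDF (European Data Format)
# ---------------------------------------------------------------------------
# Reading goes through mne's native EDF reader.  Writing is a small,
# self-contained implementation of the EDF header + 16-bit sample records
# (one 1-second data record per second of signal).

def _write_eeg_edf(rec: EEGRecording, path: Path) -> None:
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per 1-s record
    n_rec, rem = divmod(rec.n_times, spr)
    if rem:
        raise ValueError(
            "EDF writer requires a whole number of seconds of data; "
            f"got {rec.n_times} samples at {spr} Hz"
        )
    ns = rec.n_channels
    data = rec.samples

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)
    dmin, dmax = -32767, 32767

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF field too long: {text!r}")
        return b.ljust(width)

    def num(x: float, width: int) -> bytes:
        for fmt in ("%g", "%.8g", "%.6g", "%.4g", "%.3g"):
            s = fmt % x
            if len(s) <= width:
                return pad(s, width)
        raise ValueError(f"cannot format {x} in {width} EDF chars")

    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),               # patient id (anonymised)
        pad("Startdate X X X X", 80),     # recording id
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (ns + 1)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),                      # record duration, seconds
        pad(str(ns), 4),
    ])
    per_sig = b"".join([
        b"".join(pad(nm, 16) for nm in rec.channel_names),
        b"".join(pad("", 80) for _ in range(ns)),
        b"".join(pad("uV", 8) for _ in range(ns)),
        b"".join(num(v, 8) for v in pmin),
        b"".join(num(v, 8) for v in pmax),
        b"".join(pad(str(dmin), 8) for _ in range(ns)),
        b"".join(pad(str(dmax), 8) for _ in range(ns)),
        b"".join(pad("", 80) for _ in range(ns)),
        b"".join(pad(str(spr), 8) for _ in range(ns)),
        b"".join(pad("", 32) for _ in range(ns)),
    ])

    scale = (dmax - dmin) / (pmax - pmin)
    dig = np.rint((data - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        for r in range(n_rec):
            chunk = dig[:, r * spr:(r + 1) * spr]
            fh.write(chunk.tobytes())


def _read_eeg_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    return EEGRecording(
        samples=data,
        rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        onset_marker=None,
    )


def read_eeg(path: str | Path, format: str | None = None,
             rate: float | None = None) -> EEGRecording:
    """Read a scalp EEG recording from EDF or TSV.

    ``format`` is inferred from the file suffix when not given.  For TSV
    files without an embedded ``# rate=`` line, ``rate`` must be supplied.
    EDF amplitudes declared in uV are returned in microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"EEG file not found: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "tsv"
    if format == "edf":
        return _read_eeg_edf(path)
    if format == "tsv":
        return _read_eeg_tsv(path, rate)
    raise ValueError(f"unknown EEG format {format!r}")


def write_eeg(rec: EEGRecording, path: str | Path,
              format: str | None = None) -> None:
    """Write a recording as TSV (lossless) or EDF (16-bit quantized)."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "tsv"
    if format == "edf":
        _write_eeg_edf(rec, path)
    elif format == "tsv":
        _write_eeg_tsv(rec, path)
    else:
        raise ValueError(f"unknown EEG format {format!r}")


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

def read_parcellation(path: str | Path) -> ParcellationTable:
    """Read a 68-region parcellation TSV.

    Columns: ``region_id`` (1..68), ``region_name``, ``hemisphere``
    (left/right), ``vertex_ids`` (semicolon-separated, 1-based in the file).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"parcellation file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"region_id", "region_name", "hemisphere", "vertex_ids"}
    missing = required.difference(df.columns)
    if missing:
        raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
    verts = [
        [int(v) - 1 for v in str(row).split(";") if v != ""]
        for row in df["vertex_ids"]
    ]
    return ParcellationTable(
        region_ids=[int(r) for r in df["region_id"]],
        region_names=list(df["region_name"]),
        hemispheres=list(df["hemisphere"]),
        vertex_ids=verts,
    )


def default_parcellation() -> ParcellationTable:
    """The packaged Desikan--Killiany table (68 regions, one vertex each).

    The default source model places one source at each region centroid, so
    the vertex set of region *k* is simply ``{k}``.
    """
    with resources.as_file(
        resources.files("eznetsi.data").joinpath("dk_atlas.tsv")
    ) as p:
        return read_parcellation(p)


# ---------------------------------------------------------------------------
# Clinical records
# ---------------------------------------------------------------------------

def read_clinical_records(path: str | Path) -> list[ClinicalRecord]:
    """Read clinical TSV: patient_id, resected_regions (';'-separated
    1-based ids), engel_class (I/II/III/IV)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        cell = row["resected_regions"]
        regions = set() if pd.isna(cell) or cell == "" else {
            int(v) for v in str(cell).split(";")
        }
        out.append(ClinicalRecord(
            patient_id=str(row["patient_id"]),
            resected_regions=regions,
            engel_class=str(row["engel_class"]).strip(),
        ))
    return out


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def write_results(metrics_rows: Sequence[dict], report: dict | None,
                  out_dir: str | Path) -> dict[str, Path]:
    """Persist per-region scores (TSV) and a diagnostic report (JSON).

    ``metrics_rows`` is a sequence of dicts with keys ``region_id`` (1-based),
    ``band``, ``metric``, ``raw``, ``normalized``, ``is_hub``.
    Returns the paths written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc

    written: dict[str, Path] = {}
    cols = ["region_id", "band", "metric", "raw", "normalized", "is_hub"]
    tsv_path = out_dir / "node_metrics.tsv"
    if len(metrics_rows) == 0:
        logger.warning("writing header-only node metrics table (no rows)")
        df = pd.DataFrame(columns=cols)
    else:
        df = pd.DataFrame(list(metrics_rows))[cols]
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.12g",
              lineterminator="\n")
    written["metrics"] = tsv_path

    if report is not None:
        json_path = out_dir / "diagnostic_report.json"
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written["report"] = json_path
    return written


def read_results_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_results_report(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
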