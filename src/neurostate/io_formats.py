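"""Readers, writers and domain containers for every external artifact.

EEG comes in either as EDF or as a delimited channels x samples matrix with
a JSON sidecar (sampling rate, channel names, optional 2-D positions).
fMRI enters as a frames x ROIs TSV plus an atlas TSV assigning each ROI to
one of the seven canonical resting-state networks.  Clinical scores travel
in a long-format cohort TSV (one row per subject x timepoint).  All tables
are UTF-8, tab-delimited, with a mandatory header row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._edf import edf_quantization_step, write_edf

#: the Yeo-7 resting-state networks, fixed vocabulary for atlas labels
NETWORKS = ("VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN")

TIMEPOINTS = ("pre", "post")
GROUPS = ("unknown", "responder", "nonresponder")

REPORT_SCHEMA_VERSION = "1"


class FormatError(ValueError):
    """Base class for all artifact parsing failures."""


class SidecarError(FormatError):
    """Matrix EEG without a usable JSON sidecar (missing file or key)."""


class ChannelError(FormatError):
    """Duplicate or inconsistent channel names."""


class SamplingRateError(FormatError):
    """Non-positive or missing sampling rate."""


class AtlasError(FormatError):
    """Unknown network label or ROI missing from the atlas."""


class CohortError(FormatError):
    """Invalid clinical table (negative scores, duplicated rows...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EEGRecording:
    """Multichannel voltage time series (microvolts), channels x samples."""

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    positions: Optional[np.ndarray] = None   # (n_channels, 2) layout coords
    subject_id: str = ""
    timepoint: str = "pre"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("EEG data must be a 2-D channels x samples array")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("EEG data contains non-finite values")
        if self.fs <= 0:
            raise SamplingRateError(f"sampling rate must be > 0, got {self.fs}")
        names = list(self.channel_names)
        if len(names) != self.data.shape[0]:
            raise ChannelError(
                f"{len(names)} channel names for {self.data.shape[0]} rows")
        if len(set(names)) != len(names):
            raise ChannelError("duplicate channel names")
        if self.data.shape[1] == 0:
            raise FormatError("recording has zero duration")
        self.channel_names = names
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (len(names), 2):
                raise FormatError("positions must be (n_channels, 2)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclasses.dataclass
class ROITimeSeriesTable:
    """BOLD ROI time series, frames x ROIs, sampled every ``tr`` seconds."""

    data: np.ndarray
    tr: float
    roi_ids: Sequence[str]
    subject_id: str = ""
    timepoint: str = "pre"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("ROI data must be 2-D frames x ROIs")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("ROI data contains non-finite values")
        if self.tr <= 0:
            raise SamplingRateError(f"TR must be > 0, got {self.tr}")
        if self.data.shape[0] < 2:
            raise FormatError("need at least 2 frames")
        ids = list(self.roi_ids)
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate ROI ids")
        if len(ids) != self.data.shape[1]:
            raise FormatError("roi_ids do not match data columns")
        self.roi_ids = ids

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


class AtlasMap(dict):
    """Mapping ROI id -> network label, restricted to the Yeo-7 vocabulary."""

    def __init__(self, mapping: Mapping[str, str]):
        bad = sorted({v for v in mapping.values() if v not in NETWORKS})
        if bad:
            raise AtlasError(f"unknown network label(s): {', '.join(bad)}")
        super().__init__(mapping)

    def rois_of(self, network: str) -> list[str]:
        return [r for r, n in self.items() if n == network]

    def check_covers(self, roi_ids: Sequence[str]) -> None:
        missing = [r for r in roi_ids if r not in self]
        if missing:
            raise AtlasError(
                f"ROI(s) absent from atlas: {', '.join(missing[:5])}"
                + ("..." if len(missing) > 5 else ""))


COHORT_SCORE_COLUMNS = (
    "mds_updrs3_total", "tremor", "bradykinesia", "rigidity", "axial", "pdq39",
)
COHORT_COLUMNS = ("subject_id", "group", "timepoint") + COHORT_SCORE_COLUMNS


class CohortTable:
    """Long-format clinical table: one row per subject x timepoint."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
        if missing:
            raise CohortError(f"cohort table missing column(s): {missing}")
        frame = frame.loc[:, list(COHORT_COLUMNS)].reset_index(drop=True)
        if not frame["timepoint"].isin(TIMEPOINTS).all():
            raise CohortError("timepoint must be one of " + "/".join(TIMEPOINTS))
        if not frame["group"].isin(GROUPS).all():
            raise CohortError("group must be one of " + "/".join(GROUPS))
        dup = frame.duplicated(subset=["subject_id", "timepoint"])
        if dup.any():
            pairs = frame.loc[dup, ["subject_id", "timepoint"]].values.tolist()
            raise CohortError(f"duplicate (subject, timepoint) rows: {pairs}")
        scores = frame[list(COHORT_SCORE_COLUMNS)].astype(float)
        if (scores.values < 0).any():
            raise CohortError("clinical scores must be non-negative")
        sub = scores[["tremor", "bradykinesia", "rigidity", "axial"]]
        over = sub.gt(scores["mds_updrs3_total"], axis=0)
        if over.values.any():
            raise CohortError("a subscale exceeds the MDS-UPDRS III total")
        frame[list(COHORT_SCORE_COLUMNS)] = scores
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.frame["subject_id"]))

    def pivot(self, column: str = "mds_updrs3_total") -> pd.DataFrame:
        """Wide subject x timepoint view of one score column."""
        return self.frame.pivot(index="subject_id", columns="timepoint",
                                values=column)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def read_eeg(path, sidecar_path=None, subject_id: str = "",
             timepoint: str = "pre") -> EEGRecording:
    """Read EEG from EDF, or from a delimited matrix + JSON sidecar.

    Matrix dialect: rows are channels, columns are samples; TSV vs CSV is
    autodetected from the first line.  The sidecar must provide ``fs`` and
    ``channel_names`` (and may provide ``positions``).
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6   # volts -> microvolts
        return EEGRecording(data=data, fs=float(raw.info["sfreq"]),
                            channel_names=list(raw.ch_names),
                            subject_id=subject_id, timepoint=timepoint)

    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SidecarError(f"matrix EEG requires a JSON sidecar; "
                           f"{sidecar_path} not found")
    meta = json.loads(sidecar_path.read_text())
    if "fs" not in meta:
        raise SidecarError(f"sidecar {sidecar_path} lacks required key 'fs'")
    if "channel_names" not in meta:
        raise SidecarError(f"sidecar {sidecar_path} lacks 'channel_names'")
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    try:
        data = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in EEG matrix {path}: {exc}") from None
    pos = meta.get("positions")
    return EEGRecording(data=data, fs=float(meta["fs"]),
                        channel_names=list(meta["channel_names"]),
                        positions=None if pos is None else np.asarray(pos, float),
                        subject_id=subject_id or meta.get("subject_id", ""),
                        timepoint=meta.get("timepoint", timepoint))


def write_eeg_matrix(rec: EEGRecording, path, sidecar_path=None) -> None:
    """Write an EEGRecording as TSV matrix plus JSON sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter="\t", fmt="%.10g")
    meta = {"fs": rec.fs, "channel_names": list(rec.channel_names),
            "subject_id": rec.subject_id, "timepoint": rec.timepoint}
    if rec.positions is not None:
        meta["positions"] = rec.positions.tolist()
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(meta))


def write_eeg_edf(rec: EEGRecording, path) -> float:
    """Write an EEGRecording as 16-bit EDF; returns the worst-channel
    quantization step (microvolts per digital unit)."""
    write_edf(path, rec.data, rec.fs, rec.channel_names,
              patient_id=rec.subject_id or "X")
    steps = []
    for row in rec.data:
        m = max(abs(row).max(), 1.0) if abs(row).max() > 0 else 1.0
        steps.append(edf_quantization_step(-m, m))
    return max(steps)


def read_roi_table(path, tr: float, subject_id: str = "",
                   timepoint: str = "pre") -> ROITimeSeriesTable:
    """Read a frames x ROIs TSV (header row = ROI ids)."""
    frame = pd.read_csv(path, sep="\t")
    try:
        data = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in ROI table {path}: {exc}") from None
    return ROITimeSeriesTable(data=data, tr=tr, roi_ids=list(frame.columns),
                              subject_id=subject_id, timepoint=timepoint)


def write_roi_table(table: ROITimeSeriesTable, path) -> None:
    pd.DataFrame(table.data, columns=table.roi_ids).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_atlas(path) -> AtlasMap:
    """Read an atlas TSV with columns ``roi_id`` and ``network``."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("roi_id", "network"):
        if col not in frame.columns:
            raise AtlasError(f"atlas table missing column '{col}'")
    if frame["roi_id"].duplicated().any():
        raise AtlasError("duplicate roi_id in atlas")
    return AtlasMap(dict(zip(frame["roi_id"].astype(str), frame["network"])))


def write_atlas(atlas: AtlasMap, path) -> None:
    pd.DataFrame({"roi_id": list(atlas), "network": list(atlas.values())}
                 ).to_csv(path, sep="\t", index=False)


def read_cohort(path) -> CohortTable:
    frame = pd.read_csv(path, sep="\t")
    return CohortTable(frame)


def write_cohort(table: CohortTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_report(metrics: Mapping, path) -> None:
    """Write a metrics mapping as TSV (flat) or JSON (anything)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {"schema_version": REPORT_SCHEMA_VERSION, "metrics": metrics}
        path.write_text(json.dumps(payload, indent=1, default=float))
    else:
        pd.DataFrame(metrics).to_csv(path, sep="\t", index=False)


def read_report(path) -> Mapping:
    payload = json.loads(Path(path).read_text())
    if "schema_version" not in payload:
        raise FormatError("report lacks schema_version")
    return payload["metrics"]
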