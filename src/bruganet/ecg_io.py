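"""Reading, writing and quality control of digitized multi-lead ECG exports.

Two instrument dialects are supported: ``claris`` (2000 Hz sampling,
5 µV amplitude quantum) and ``mortara`` (1000 Hz, 1 µV), plus a
``synthetic`` dialect used by the cohort generator.  Amplitudes are held
internally in millivolts as floats; quantization to instrument counts is
purely an I/O concern.

The on-disk layout is a single text file per record::

    # fs=<Hz> resolution_uV=<q> leads=<comma-separated labels>
    <count lead 1>\t<count lead 2>\t...

one row per sample, one integer count column per lead, where
``mV = count * resolution_uV / 1000``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DIALECTS",
    "CANONICAL_LEADS",
    "RECORDED_LEADS",
    "LeadSet",
    "ECGRecord",
    "QCPolicy",
    "LeadMappingError",
    "ECGParseError",
    "read_ecg_export",
    "write_ecg_export",
    "derive_lead_iii",
    "qc_screen",
]

#: dialect name -> (sampling frequency Hz, amplitude resolution µV)
DIALECTS: dict[str, tuple[float, float]] = {
    "claris": (2000.0, 5.0),
    "mortara": (1000.0, 1.0),
    "synthetic": (500.0, 1.0),
}

#: leads acquired by both instruments (two limb + six high-precordial)
RECORDED_LEADS: tuple[str, ...] = ("L1", "L2", "V1", "V2", "V3", "V4", "V5", "V6")

#: canonical classifier lead order: recorded leads plus derived lead III,
#: excluding the unipolar limb leads aVR/aVL/aVF
CANONICAL_LEADS: tuple[str, ...] = ("L1", "L2", "L3", "V1", "V2", "V3", "V4", "V5", "V6")

# common aliases found in clinical text exports
_LEAD_ALIASES = {
    "I": "L1", "II": "L2", "III": "L3",
    "LEAD1": "L1", "LEAD2": "L2", "LEAD3": "L3",
    "L1": "L1", "L2": "L2", "L3": "L3",
    "V1": "V1", "V2": "V2", "V3": "V3", "V4": "V4", "V5": "V5", "V6": "V6",
}


class LeadMappingError(ValueError):
    """A lead label in a file could not be mapped onto the canonical set."""


class ECGParseError(ValueError):
    """Malformed ECG export file."""


@dataclass(frozen=True)
class LeadSet:
    """An ordered set of lead labels with a placement convention."""

    names: tuple[str, ...] = CANONICAL_LEADS
    convention: str = "high_precordial"

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("lead names must be unique")
        forbidden = {"aVR", "aVL", "aVF"} & set(self.names)
        if forbidden:
            raise ValueError(f"unipolar limb leads are excluded: {sorted(forbidden)}")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)


@dataclass
class ECGRecord:
    """A raw multi-lead trace in physical units (mV).

    Parameters
    ----------
    signals
        Mapping of lead label to a 1-D amplitude array in millivolts.
        All leads must have equal length.
    fs
        Sampling frequency in Hz.
    resolution_uV
        Amplitude quantum of the acquiring instrument in microvolts.
    dialect
        Provenance dialect: ``"claris"``, ``"mortara"`` or ``"synthetic"``.
    """

    signals: dict[str, np.ndarray]
    fs: float
    resolution_uV: float
    dialect: str = "synthetic"
    patient_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.signals:
            raise ValueError("record has no leads")
        self.signals = {k: np.asarray(v, dtype=float) for k, v in self.signals.items()}
        lengths = {len(v) for v in self.signals.values()}
        if len(lengths) != 1:
            raise ValueError(f"leads have unequal lengths: {sorted(lengths)}")
        for lead, x in self.signals.items():
            if not np.all(np.isfinite(x)):
                raise ValueError(f"non-finite amplitudes in lead {lead}")

    @property
    def leads(self) -> tuple[str, ...]:
        return tuple(self.signals)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.signals.values())))

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def __getitem__(self, lead: str) -> np.ndarray:
        return self.signals[lead]


def _canonical_label(raw: str) -> str:
    key = raw.strip().upper().replace("-", "")
    if key not in _LEAD_ALIASES:
        raise LeadMappingError(f"unknown lead label {raw!r}")
    return _LEAD_ALIASES[key]


_HEADER_RE = re.compile(
    r"^#\s*fs=(?P<fs>[\d.]+)\s+resolution_uV=(?P<res>[\d.]+)\s+leads=(?P<leads>\S+)"
)


def read_ecg_export(path: str | Path, dialect: str = "synthetic",
                    patient_id: str | None = None) -> ECGRecord:
    """Read a canonical text export into an :class:`ECGRecord` in mV.

    Integer counts in the file are converted with
    ``mV = count * resolution_uV / 1000``.  If the header's sampling rate
    disagrees with the dialect's nominal rate, the file value wins and a
    warning is emitted.
    """
    import warnings

    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        header = fh.readline()
        m = _HEADER_RE.match(header)
        if not m:
            raise ECGParseError(f"{path}: missing or malformed header line")
        fs = float(m.group("fs"))
        res = float(m.group("res"))
        labels = [_canonical_label(s) for s in m.group("leads").split(",")]
        if len(set(labels)) != len(labels):
            raise LeadMappingError(f"{path}: duplicate lead labels")
        rows = []
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise ECGParseError(f"{path}: non-numeric data at row {i}") from exc
    if not rows:
        raise ECGParseError(f"{path}: no sample rows")
    data = np.asarray(rows, dtype=float)
    if data.shape[1] != len(labels):
        raise ECGParseError(
            f"{path}: {data.shape[1]} columns but {len(labels)} leads declared")
    nominal_fs = DIALECTS[dialect][0]
    if dialect != "synthetic" and abs(fs - nominal_fs) > 1e-9:
        warnings.warn(
            f"{path}: header fs={fs} Hz differs from {dialect} nominal "
            f"{nominal_fs} Hz; using file value", stacklevel=2)
    signals = {lab: data[:, j] * res / 1000.0 for j, lab in enumerate(labels)}
    return ECGRecord(signals=signals, fs=fs, resolution_uV=res, dialect=dialect,
                     patient_id=patient_id or path.stem)


def write_ecg_export(record: ECGRecord, path: str | Path,
                     dialect: str | None = None) -> Path:
    """Write *record* as a canonical text export, re-quantized to the
    dialect's amplitude resolution."""
    path = Path(path)
    dialect = dialect or record.dialect
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    res = DIALECTS[dialect][1]
    leads = list(record.leads)
    counts = np.column_stack(
        [np.rint(record[lead] * 1000.0 / res).astype(np.int64) for lead in leads])
    header = f"# fs={record.fs:g} resolution_uV={res:g} leads={','.join(leads)}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, counts, fmt="%d", delimiter="\t")
    return path


def quantize(x: np.ndarray, resolution_uV: float) -> np.ndarray:
    """Snap amplitudes (mV) onto the instrument grid of *resolution_uV*."""
    q = resolution_uV / 1000.0
    return np.rint(np.asarray(x, dtype=float) / q) * q


def derive_lead_iii(record: ECGRecord) -> ECGRecord:
    """Return a record with derived limb lead III (L3 = L2 - L1) inserted
    in canonical position if it is absent.  Einthoven's law."""
    if "L3" in record.signals:
        return record
    if not {"L1", "L2"} <= set(record.signals):
        raise LeadMappingError("cannot derive lead III without L1 and L2")
    ordered: dict[str, np.ndarray] = {}
    for lead in record.leads:
        ordered[lead] = record.signals[lead]
        if lead == "L2":
            ordered["L3"] = record.signals["L2"] - record.signals["L1"]
    return ECGRecord(signals=ordered, fs=record.fs,
                     resolution_uV=record.resolution_uV, dialect=record.dialect,
                     patient_id=record.patient_id, metadata=dict(record.metadata))


@dataclass(frozen=True)
class QCPolicy:
    """Automated artifact-screening thresholds.

    A record fails if any lead is flat for longer than ``max_flat_s``
    seconds, saturates for ``clip_run`` or more consecutive samples at or
    above ``clip_level_mV``, carries broadband (>40 Hz) noise with RMS
    above ``max_hf_rms_mV``, or is shorter than ``min_duration_s``.
    """

    max_flat_s: float = 2.0
    clip_run: int = 3
    clip_level_mV: float = 2.5
    max_hf_rms_mV: float = 0.15
    min_duration_s: float = 10.0


def _max_run_length(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate(([0], mask.astype(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    return int(np.max(edges[1::2] - edges[0::2]))


def qc_screen(record: ECGRecord, policy: QCPolicy | None = None
              ) -> tuple[bool, list[str]]:
    """Screen a record for measurement artifacts.

    Returns ``(passed, reasons)``; ``reasons`` lists every failure found.
    Always returns a verdict, never raises.
    """
    from scipy import signal as sig

    policy = policy or QCPolicy()
    reasons: list[str] = []
    if record.duration < policy.min_duration_s:
        reasons.append(
            f"duration {record.duration:.1f} s < {policy.min_duration_s:g} s")
    flat_run = int(policy.max_flat_s * record.fs)
    # 40 Hz high-pass for broadband-noise power; guard very low fs
    sos = None
    if record.fs > 100:
        sos = sig.butter(2, 40.0, btype="highpass", fs=record.fs, output="sos")
    for lead, x in record.signals.items():
        if _max_run_length(np.diff(x) == 0) >= flat_run:
            reasons.append(f"flat lead {lead}")
        at_ceiling = np.abs(x) >= policy.clip_level_mV
        if _max_run_length(at_ceiling) >= policy.clip_run:
            reasons.append(f"clipping in lead {lead}")
        if sos is not None:
            hf = sig.sosfiltfilt(sos, x)
            if float(np.sqrt(np.mean(hf**2))) > policy.max_hf_rms_mV:
                reasons.append(f"broadband noise in lead {lead}")
    return (len(reasons) == 0, reasons)
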