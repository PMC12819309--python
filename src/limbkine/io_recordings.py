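"""On-disk trial format, cohort manifest, and recording validation.

A trial is one 20-s, 100-Hz IMU recording for one leg, task and repetition:
sagittal-plane foot angle (pitch, degrees) from the foot-mounted sensor and
triaxial acceleration (m/s^2, z vertical) from the ankle-mounted sensor.
Trials are stored as plain UTF-8 CSV with a small ``# key=value`` metadata
header so that fixtures are reproducible and diffable.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

TRIAL_MAGIC = "# limbkine-trial v1"
TRIAL_COLUMNS = ["t_s", "pitch_deg", "acc_x_ms2", "acc_y_ms2", "acc_z_ms2"]
MANIFEST_COLUMNS = [
    "participant_id", "dominant_leg", "task", "leg", "trial_index", "path",
]

TASKS = ("TT", "LA")
LEGS = ("left", "right")

#: tolerance on timestamp uniformity, seconds
TIME_TOLERANCE = 1e-6
#: a study-style trial must last between these bounds, seconds
DURATION_BOUNDS = (10.0, 25.0)
#: durations outside this band are flagged with a warning, seconds
DURATION_WARN_BAND = (19.0, 21.0)


class TrialFormatError(ValueError):
    """Raised when a trial file does not follow the CSV dialect."""


class TrialValidationError(ValueError):
    """Raised when a recording violates a structural invariant."""


@dataclasses.dataclass
class TrialRecording:
    """One multi-channel IMU recording for a single leg/task/trial.

    ``pitch`` is the sagittal-plane foot angle in degrees (negative = toes
    elevated); ``acc`` holds ankle-sensor acceleration in m/s^2 with the
    vertical channel in column 2.
    """

    participant_id: str
    task: str
    leg: str
    dominant: bool
    trial_index: int
    sample_rate: float
    t: np.ndarray
    pitch: np.ndarray
    acc: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.ndim == 1:
            self.acc = np.column_stack(
                [np.zeros_like(self.acc), np.zeros_like(self.acc), self.acc]
            )

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        """Nominal trial length n/fs in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def acc_vertical(self) -> np.ndarray:
        return self.acc[:, 2]

    def replace(self, **changes) -> "TrialRecording":
        return dataclasses.replace(self, **changes)

    def validate(self) -> None:
        """Check structural invariants; raise :class:`TrialValidationError`.

        Timestamps must be strictly increasing and uniform to within 1e-6 s
        of 1/sample_rate, channels must be complete (no NaN), and the
        duration must be study-plausible (10-25 s; a warning is emitted
        outside 19-21 s).
        """
        if self.task not in TASKS:
            raise TrialValidationError(f"unknown task {self.task!r}")
        if self.leg not in LEGS:
            raise TrialValidationError(f"unknown leg {self.leg!r}")
        if not 1 <= int(self.trial_index) <= 5:
            raise TrialValidationError(
                f"trial_index must be 1..5, got {self.trial_index}"
            )
        if self.sample_rate <= 0:
            raise TrialValidationError("sample_rate must be positive")
        n = self.n_samples
        if self.pitch.shape != (n,) or self.acc.shape != (n, 3):
            raise TrialValidationError(
                "channel lengths differ: "
                f"t={n}, pitch={self.pitch.shape}, acc={self.acc.shape}"
            )
        if n < 2:
            raise TrialValidationError(
                f"recording of {n} sample(s) is below the minimum duration"
            )
        dt = 1.0 / self.sample_rate
        dev = np.abs(np.diff(self.t) - dt)
        bad = np.nonzero(dev > TIME_TOLERANCE)[0]
        if bad.size:
            i = int(bad[0])
            raise TrialValidationError(
                f"non-uniform timestamps: step t[{i}]->t[{i + 1}] is "
                f"{self.t[i + 1] - self.t[i]:.6g} s (expected {dt:.6g} s) "
                f"at sample index {i + 1}"
            )
        for name, arr in (("pitch", self.pitch), ("acc", self.acc)):
            if not np.all(np.isfinite(arr)):
                raise TrialValidationError(f"channel {name} has missing samples")
        lo, hi = DURATION_BOUNDS
        if not lo <= self.duration <= hi:
            raise TrialValidationError(
                f"duration {self.duration:.2f} s outside valid range "
                f"[{lo:g}, {hi:g}] s"
            )
        wlo, whi = DURATION_WARN_BAND
        if not wlo <= self.duration <= whi:
            warnings.warn(
                f"trial duration {self.duration:.2f} s outside the nominal "
                f"20-s protocol band [{wlo:g}, {whi:g}] s",
                stacklevel=2,
            )


def write_trial(rec: TrialRecording, path: str | Path) -> None:
    """Write ``rec`` to ``path`` in the trial CSV dialect.

    Floats are written with full round-trip precision so that
    ``read_trial(write_trial(rec))`` is the identity on all channels.
    """
    rec.validate()
    path = Path(path)
    df = pd.DataFrame(
        {
            "t_s": rec.t,
            "pitch_deg": rec.pitch,
            "acc_x_ms2": rec.acc[:, 0],
            "acc_y_ms2": rec.acc[:, 1],
            "acc_z_ms2": rec.acc[:, 2],
        }
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(TRIAL_MAGIC + "\n")
        fh.write(f"# participant_id={rec.participant_id}\n")
        fh.write(f"# task={rec.task}\n")
        fh.write(f"# leg={rec.leg}\n")
        fh.write(f"# dominant={'true' if rec.dominant else 'false'}\n")
        fh.write(f"# trial_index={int(rec.trial_index)}\n")
        fh.write(f"# sample_rate_hz={rec.sample_rate!r}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_trial(path: str | Path, manifest_entry: dict | None = None) -> TrialRecording:
    """Read and validate a trial CSV written in the dialect of this package.

    If ``manifest_entry`` is given (a mapping with any of participant_id,
    task, leg, trial_index), its values are cross-checked against the file
    header and a mismatch raises :class:`TrialFormatError`.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first != TRIAL_MAGIC:
            raise TrialFormatError(
                f"{path}: not a limbkine trial file (header {first!r})"
            )
        meta: dict[str, str] = {}
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise TrialFormatError(f"{path}: malformed metadata line {line!r}")
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
            line = fh.readline()
        header = line.rstrip("\n")
        if header.split(",") != TRIAL_COLUMNS:
            raise TrialFormatError(
                f"{path}: unexpected column header {header!r}"
            )
        df = pd.read_csv(io.StringIO(header + "\n" + fh.read()))
    required = ("participant_id", "task", "leg", "dominant", "trial_index",
                "sample_rate_hz")
    missing = [k for k in required if k not in meta]
    if missing:
        raise TrialFormatError(f"{path}: missing metadata keys {missing}")
    rec = TrialRecording(
        participant_id=meta["participant_id"],
        task=meta["task"],
        leg=meta["leg"],
        dominant=meta["dominant"].lower() == "true",
        trial_index=int(meta["trial_index"]),
        sample_rate=float(meta["sample_rate_hz"]),
        t=df["t_s"].to_numpy(),
        pitch=df["pitch_deg"].to_numpy(),
        acc=df[["acc_x_ms2", "acc_y_ms2", "acc_z_ms2"]].to_numpy(),
    )
    if manifest_entry:
        for key in ("participant_id", "task", "leg"):
            if key in manifest_entry and str(manifest_entry[key]) != getattr(rec, key):
                raise TrialFormatError(
                    f"{path}: header {key}={getattr(rec, key)!r} does not match "
                    f"manifest {manifest_entry[key]!r}"
                )
        if "trial_index" in manifest_entry and \
                int(manifest_entry["trial_index"]) != rec.trial_index:
            raise TrialFormatError(
                f"{path}: header trial_index={rec.trial_index} does not match "
                f"manifest {manifest_entry['trial_index']}"
            )
    rec.validate()
    return rec


def rezero_pitch(rec: TrialRecording, quiet_window: float = 0.5) -> TrialRecording:
    """Software analogue of the pre-trial orientation reset.

    Subtracts the median pitch of the first ``quiet_window`` seconds so that
    the neutral (foot flat) pitch is ~0 deg, which keeps contact peaks above
    the -3 deg detection threshold. Idempotent to numerical precision.
    """
    if quiet_window <= 0:
        raise ValueError("quiet_window must be positive")
    if quiet_window > rec.duration:
        raise ValueError(
            f"quiet_window {quiet_window:g} s exceeds trial duration "
            f"{rec.duration:g} s"
        )
    mask = rec.t < rec.t[0] + quiet_window
    offset = float(np.median(rec.pitch[mask]))
    return rec.replace(pitch=rec.pitch - offset)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest = manifest.loc[:, MANIFEST_COLUMNS]
    manifest.to_csv(path, index=False, lineterminator="\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: manifest missing columns {missing}")
    validate_manifest(df)
    return df


def validate_manifest(manifest: pd.DataFrame) -> None:
    """Check manifest invariants: 1..5 trials per (participant, task, leg)
    and a consistent dominant leg per participant."""
    for pid, grp in manifest.groupby("participant_id"):
        doms = grp["dominant_leg"].unique()
        if len(doms) != 1 or doms[0] not in LEGS:
            raise TrialValidationError(
                f"participant {pid}: inconsistent dominant_leg {list(doms)}"
            )
    counts = manifest.groupby(["participant_id", "task", "leg"]).size()
    if (counts < 1).any() or (counts > 5).any():
        bad = counts[(counts < 1) | (counts > 5)]
        raise TrialValidationError(
            f"manifest has conditions with trial counts outside 1..5: {bad}"
        )
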