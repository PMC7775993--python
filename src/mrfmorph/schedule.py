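"""MRF acquisition schedule: flip-angle train, timing, and segment structure.

The sequence modelled here is an inversion-prepared, gradient-spoiled SSFP
(FISP-type) fingerprinting acquisition: an adiabatic inversion pulse followed
by a long train of variable flip-angle hard pulses at constant TR/TE, with an
unbalanced z-spoiler gradient each TR.  The flip-angle pattern is a triangular
ramp (linear rise, linear descent) followed by a constant plateau, and the
whole train is repeated over a number of acquisition segments to fill k-space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionSchedule",
    "build_schedule",
    "acquisition_duration",
    "save_schedule",
    "load_schedule",
]


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Flip-angle train and timing of one MRF acquisition.

    Parameters
    ----------
    flip_angles_deg
        RF flip angle per excitation pulse, degrees, length ``n_pulses``.
    tr_ms, te_ms
        Repetition and echo time in milliseconds, constant over the train.
    n_segments
        Number of times the train is repeated during the acquisition
        (each segment re-rotates the readout trajectory; the spin dynamics
        of one segment carry over into the next).
    inversion
        Whether an adiabatic inversion pulse precedes each segment's train.
    spoiler_dephasing_cycles
        Gradient dephasing per TR in units of 2*pi across a voxel.  The
        default 2 encodes 4*pi intra-voxel dephasing.  Any whole number of
        cycles acts as one configuration-order shift in the extended phase
        graph picture.
    """

    flip_angles_deg: np.ndarray
    tr_ms: float
    te_ms: float
    n_segments: int = 1
    inversion: bool = True
    spoiler_dephasing_cycles: int = 2

    def __post_init__(self) -> None:
        fa = np.asarray(self.flip_angles_deg, dtype=float)
        object.__setattr__(self, "flip_angles_deg", fa)
        if fa.ndim != 1 or fa.size < 1:
            raise ValueError("flip_angles_deg must be a non-empty 1-D sequence")
        if np.any(fa < 0.0) or np.any(fa > 180.0):
            raise ValueError("flip angles must lie in [0, 180] degrees")
        if not (self.tr_ms > self.te_ms >= 0.0):
            raise ValueError("require tr_ms > te_ms >= 0")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.spoiler_dephasing_cycles < 1:
            raise ValueError("spoiler_dephasing_cycles must be >= 1 (unbalanced sequence)")

    @property
    def n_pulses(self) -> int:
        return int(self.flip_angles_deg.size)

    def fingerprint(self) -> str:
        """Stable hex digest of everything that determines the signal model."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.flip_angles_deg).tobytes())
        h.update(
            f"{self.tr_ms!r}|{self.te_ms!r}|{self.n_segments}|"
            f"{self.inversion}|{self.spoiler_dephasing_cycles}".encode()
        )
        return h.hexdigest()[:16]


def build_schedule(
    n_pulses: int = 880,
    ramp_up_len: int = 440,
    ramp_down_len: int = 220,
    peak_flip_deg: float = 70.0,
    constant_flip_deg: float = 15.0,
    start_flip_deg: float = 1.0,
    tr_ms: float = 12.0,
    te_ms: float = 0.5,
    n_segments: int = 56,
    inversion: bool = True,
    spoiler_dephasing_cycles: int = 2,
) -> AcquisitionSchedule:
    """Construct the triangular-ramp-plus-plateau flip-angle schedule.

    The train rises linearly from ``start_flip_deg`` to ``peak_flip_deg``
    over ``ramp_up_len`` pulses, descends linearly to ``constant_flip_deg``
    over ``ramp_down_len`` pulses, and stays at ``constant_flip_deg`` for the
    remainder.  Defaults give the 880-pulse / 56-segment acquisition at
    TR 12 ms, TE 0.5 ms.  The peak/plateau amplitudes are configurable; all
    signal-model code is parameterised over the schedule, so nothing below
    depends on these defaults.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be positive")
    if ramp_up_len < 0 or ramp_down_len < 0:
        raise ValueError("ramp lengths must be non-negative")
    if ramp_up_len + ramp_down_len > n_pulses:
        raise ValueError("ramp lengths exceed n_pulses")
    for name, val in (
        ("peak_flip_deg", peak_flip_deg),
        ("constant_flip_deg", constant_flip_deg),
        ("start_flip_deg", start_flip_deg),
    ):
        if not (0.0 <= val <= 180.0):
            raise ValueError(f"{name} must lie in [0, 180]")

    fa = np.empty(n_pulses, dtype=float)
    if ramp_up_len > 0:
        fa[:ramp_up_len] = np.linspace(start_flip_deg, peak_flip_deg, ramp_up_len)
    if ramp_down_len > 0:
        # descend from the peak; the first down pulse steps off the peak value
        down = np.linspace(peak_flip_deg, constant_flip_deg, ramp_down_len + 1)[1:]
        fa[ramp_up_len : ramp_up_len + ramp_down_len] = down
    fa[ramp_up_len + ramp_down_len :] = constant_flip_deg
    return AcquisitionSchedule(
        flip_angles_deg=fa,
        tr_ms=tr_ms,
        te_ms=te_ms,
        n_segments=n_segments,
        inversion=inversion,
        spoiler_dephasing_cycles=spoiler_dephasing_cycles,
    )


def acquisition_duration(schedule: AcquisitionSchedule) -> float:
    """Total acquisition time in seconds: TR * n_pulses * n_segments.

    Inversion pulses and inter-segment gaps are counted as zero time; at the
    default parameters (12 ms x 880 x 56) this reproduces the nominal
    9 min 51 s scan time, so dead time is negligible in this accounting.
    """
    return schedule.tr_ms * schedule.n_pulses * schedule.n_segments / 1000.0


# ---------------------------------------------------------------------------
# plain-text serialization: key-value header + two-column table
# ---------------------------------------------------------------------------

def save_schedule(schedule: AcquisitionSchedule, path: str | Path) -> None:
    """Write a schedule as '# key value' header lines plus (index, degrees) rows."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# tr_ms {schedule.tr_ms!r}\n")
        fh.write(f"# te_ms {schedule.te_ms!r}\n")
        fh.write(f"# n_segments {schedule.n_segments}\n")
        fh.write(f"# inversion {int(schedule.inversion)}\n")
        fh.write(f"# spoiler_dephasing_cycles {schedule.spoiler_dephasing_cycles}\n")
        for i, a in enumerate(schedule.flip_angles_deg):
            fh.write(f"{i}\t{float(a)!r}\n")


def load_schedule(path: str | Path) -> AcquisitionSchedule:
    header: dict[str, str] = {}
    angles: list[float] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition(" ")
                header[key] = val
            else:
                angles.append(float(line.split("\t")[1]))
    return AcquisitionSchedule(
        flip_angles_deg=np.asarray(angles),
        tr_ms=float(header["tr_ms"]),
        te_ms=float(header["te_ms"]),
        n_segments=int(header["n_segments"]),
        inversion=bool(int(header.get("inversion", "1"))),
        spoiler_dephasing_cycles=int(header.get("spoiler_dephasing_cycles", "2")),
    )
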