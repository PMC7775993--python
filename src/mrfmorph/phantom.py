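"""Digital brain phantom and the scan-rescan / two-method study design.

The phantom is a labeled 3-D volume standing in for volunteer anatomy: an
ellipsoidal white-matter core wrapped in a cortical gray-matter shell and a
CSF rim, with four subcortical gray-matter blobs (thalamus-, putamen-,
caudate- and hippocampus-like), each tissue carrying literature T1/T2 values.
Per-subject multiplicative jitter of the relaxation times and structure radii
creates a cohort with realistic between-subject variance.

A scan session resamples the phantom's continuous T1/T2 property fields
through a rigid-body repositioning transform (trilinear), so partial-volume
mixing at tissue edges differs between scan and rescan — the mechanism that
drives realistic nonzero test-retest variability.  Per-voxel signal
evolutions come from the EPG engine, cached over (T1, T2) quantized to 1 ms,
with i.i.d. complex Gaussian measurement noise added in the time domain.

A second "conventional" measurement arm returns morphometry metrics derived
from the ground truth plus a configurable systematic bias and seeded noise,
emulating the comparison of fingerprinting-derived morphometry against a
conventional T1-weighted acquisition that segments slightly differently
(thickness bias 0.17 mm by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .epg import simulate_many
from .schedule import AcquisitionSchedule

__all__ = [
    "TISSUES",
    "Phantom",
    "ScanSession",
    "RigidTransform",
    "generate_phantom",
    "simulate_session",
    "session_signal_volume",
    "conventional_arm",
]

# label -> (name, T1 ms, T2 ms): literature 3 T brain values
TISSUES: dict[int, tuple[str, float, float]] = {
    1: ("csf", 4000.0, 2000.0),
    2: ("white_matter", 800.0, 40.0),
    3: ("cortical_gm", 1300.0, 80.0),
    4: ("thalamus", 1200.0, 65.0),
    5: ("putamen", 1100.0, 60.0),
    6: ("caudate", 1300.0, 70.0),
    7: ("hippocampus", 1400.0, 80.0),
}

CORTICAL_LABEL = 3
SUBCORTICAL_LABELS = (4, 5, 6, 7)

# blob centers/radii as fractions of the volume shape
_SUBCORTICAL_GEOMETRY = {
    4: ((0.42, 0.50, 0.50), (0.055, 0.075, 0.055)),  # thalamus-like
    5: ((0.58, 0.42, 0.52), (0.050, 0.065, 0.050)),  # putamen-like
    6: ((0.58, 0.58, 0.55), (0.045, 0.060, 0.045)),  # caudate-like
    7: ((0.50, 0.62, 0.42), (0.040, 0.075, 0.040)),  # hippocampus-like
}


@dataclass
class Phantom:
    """Labeled tissue geometry with per-tissue relaxation properties."""

    labels: np.ndarray  # integer volume; 0 background
    tissue_table: pd.DataFrame  # region_id, region_name, t1_ms, t2_ms
    voxel_mm: float
    seed: int

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_mm] * 3 + [1.0])

    def property_fields(self) -> tuple[np.ndarray, np.ndarray]:
        """Continuous per-voxel (T1, T2) fields in ms; 0 in background."""
        t1 = np.zeros(self.shape)
        t2 = np.zeros(self.shape)
        for row in self.tissue_table.itertuples():
            sel = self.labels == row.region_id
            t1[sel] = row.t1_ms
            t2[sel] = row.t2_ms
        return t1, t2


@dataclass(frozen=True)
class RigidTransform:
    """Six-parameter rigid repositioning: rotations (deg) and translations (mm)."""

    rot_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    trans_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def is_identity(self) -> bool:
        return all(v == 0.0 for v in self.rot_deg + self.trans_mm)

    def magnitude(self) -> float:
        """Scalar motion magnitude (deg/mm mixed) used by exclusion rules."""
        return float(
            np.linalg.norm(self.rot_deg) + np.linalg.norm(self.trans_mm)
        )

    def matrix(self) -> np.ndarray:
        rx, ry, rz = np.deg2rad(self.rot_deg)

        def _rx(a):
            c, s = np.cos(a), np.sin(a)
            return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

        def _ry(a):
            c, s = np.cos(a), np.sin(a)
            return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

        def _rz(a):
            c, s = np.cos(a), np.sin(a)
            return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])

        return _rz(rz) @ _ry(ry) @ _rx(rx)


def _ellipsoid(shape, center_frac, radii_frac) -> np.ndarray:
    grid = np.indices(shape).astype(float)
    c = [f * (s - 1) for f, s in zip(center_frac, shape)]
    r = [max(f * s, 1.0) for f, s in zip(radii_frac, shape)]
    d = sum(((grid[i] - c[i]) / r[i]) ** 2 for i in range(3))
    return d <= 1.0


def generate_phantom(
    shape: tuple[int, int, int] = (96, 96, 96),
    seed: int = 0,
    voxel_mm: float = 1.0,
    shell_thickness_mm: float = 2.5,
    csf_thickness_mm: float = 2.0,
    jitter: float = 0.03,
    tissues: dict[int, tuple[str, float, float]] | None = None,
) -> Phantom:
    """Build one subject's labeled phantom, deterministic given ``seed``.

    Per-subject variation: tissue T1/T2 and structure radii each get an
    independent multiplicative factor drawn uniformly from
    ``[1 - jitter, 1 + jitter]``.
    """
    shape = tuple(int(s) for s in np.broadcast_to(shape, (3,)))
    if min(shape) < 32:
        raise ValueError("shape must be at least 32 voxels per axis")
    rng = np.random.default_rng(seed)
    tissues = dict(tissues if tissues is not None else TISSUES)

    def jit() -> float:
        return float(rng.uniform(1.0 - jitter, 1.0 + jitter))

    labels = np.zeros(shape, dtype=np.int16)
    wm = _ellipsoid(shape, (0.5, 0.5, 0.5), tuple(0.30 * jit() for _ in range(3)))

    # cortical shell and CSF rim by distance from the structures they wrap
    dist_wm = ndimage.distance_transform_edt(~wm, sampling=voxel_mm)
    gm = (dist_wm <= shell_thickness_mm) & ~wm
    brain = wm | gm
    dist_brain = ndimage.distance_transform_edt(~brain, sampling=voxel_mm)
    csf = (dist_brain <= csf_thickness_mm) & ~brain

    labels[csf] = 1
    labels[wm] = 2
    labels[gm] = CORTICAL_LABEL
    for lab in SUBCORTICAL_LABELS:
        center, radii = _SUBCORTICAL_GEOMETRY[lab]
        blob = _ellipsoid(shape, center, tuple(r * jit() for r in radii)) & wm
        labels[blob] = lab

    rows = []
    for lab, (name, t1, t2) in tissues.items():
        rows.append((lab, name, t1 * jit(), t2 * jit()))
    table = pd.DataFrame(rows, columns=["region_id", "region_name", "t1_ms", "t2_ms"])

    present = set(np.unique(labels)) - {0}
    if present != set(tissues):
        missing = set(tissues) - present
        raise ValueError(f"shape {shape} too small: structures {missing} are empty")
    return Phantom(labels=labels, tissue_table=table, voxel_mm=voxel_mm, seed=seed)


# ---------------------------------------------------------------------------
# scan sessions
# ---------------------------------------------------------------------------


@dataclass
class ScanSession:
    """One repositioned, noised acquisition of a phantom.

    Signals are stored compactly as quantized per-voxel (T1, T2) fields;
    time-courses are simulated on demand (cached per unique pair) and the
    measurement noise is reproducible from ``seed``.
    """

    t1q_ms: np.ndarray  # quantized resampled T1 field (0 outside mask)
    t2q_ms: np.ndarray
    labels: np.ndarray  # nearest-neighbour resampled labels (segmentation stand-in)
    mask: np.ndarray
    rigid_transform: RigidTransform
    noise_sigma: float
    seed: int
    voxel_mm: float
    quant_ms: float = 1.0


def _resample(vol: np.ndarray, transform: RigidTransform, voxel_mm: float, order: int):
    if transform.is_identity:
        return vol.copy()
    rot = transform.matrix()
    center = (np.asarray(vol.shape) - 1) / 2.0
    shift_vox = np.asarray(transform.trans_mm) / voxel_mm
    # output[x] = input[R^-1 @ (x - c - t) + c]
    inv = rot.T
    offset = center - inv @ (center + shift_vox)
    return ndimage.affine_transform(
        vol, inv, offset=offset, order=order, mode="constant", cval=0.0
    )


def simulate_session(
    phantom: Phantom,
    transform: RigidTransform | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    quant_ms: float = 1.0,
) -> ScanSession:
    """Reposition the phantom and set up one acquisition's voxel properties.

    The continuous T1/T2 fields are resampled trilinearly (partial-volume
    mixing at edges), labels by nearest neighbour, then the fields are
    quantized to ``quant_ms`` for the simulation cache.  Voxels whose
    resampled relaxation times fall to zero leave the mask.
    """
    transform = transform or RigidTransform()
    if abs(np.linalg.det(transform.matrix())) < 1e-9:
        raise ValueError("singular transform")
    t1, t2 = phantom.property_fields()
    t1r = _resample(t1, transform, phantom.voxel_mm, order=1)
    t2r = _resample(t2, transform, phantom.voxel_mm, order=1)
    labr = _resample(phantom.labels.astype(np.int16), transform, phantom.voxel_mm, order=0)
    t1q = np.maximum(np.round(t1r / quant_ms), 0) * quant_ms
    t2q = np.maximum(np.round(t2r / quant_ms), 0) * quant_ms
    mask = (labr > 0) & (t1q > 0) & (t2q > 0)
    t1q[~mask] = 0.0
    t2q[~mask] = 0.0
    labr[~mask] = 0
    return ScanSession(
        t1q_ms=t1q,
        t2q_ms=t2q,
        labels=labr,
        mask=mask,
        rigid_transform=transform,
        noise_sigma=float(noise_sigma),
        seed=int(seed),
        voxel_mm=phantom.voxel_mm,
        quant_ms=quant_ms,
    )


def session_unique_signals(
    session: ScanSession,
    schedule: AcquisitionSchedule,
    cache: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate time-courses for the session's unique (T1, T2) pairs.

    Returns ``(inverse, signals)`` where ``signals[inverse[i]]`` is the
    noiseless evolution of masked voxel i (mask scanned in C order).  An
    optional cross-session ``cache`` maps (t1, t2) -> signal row.
    """
    pairs = np.stack([session.t1q_ms[session.mask], session.t2q_ms[session.mask]], 1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    signals = np.empty((uniq.shape[0], schedule.n_pulses), dtype=complex)
    if cache is None:
        todo = np.arange(uniq.shape[0])
    else:
        todo = []
        for i, (a, b) in enumerate(uniq):
            hit = cache.get((a, b))
            if hit is None:
                todo.append(i)
            else:
                signals[i] = hit
        todo = np.asarray(todo, dtype=int)
    if todo.size:
        fresh = simulate_many(schedule, uniq[todo, 0], uniq[todo, 1])
        signals[todo] = fresh
        if cache is not None:
            for i, row in zip(todo, fresh):
                cache[(uniq[i, 0], uniq[i, 1])] = row
    return inverse, signals


def session_signal_volume(
    session: ScanSession, schedule: AcquisitionSchedule
) -> np.ndarray:
    """Materialize the full 4-D (x, y, z, t) noisy signal volume.

    Convenience for small phantoms; the pipeline matches block-wise instead.
    """
    inverse, signals = session_unique_signals(session, schedule)
    vol = np.zeros(session.mask.shape + (schedule.n_pulses,), dtype=complex)
    voxels = signals[inverse]
    if session.noise_sigma > 0:
        rng = np.random.default_rng(session.seed)
        noise = rng.standard_normal(voxels.shape) + 1j * rng.standard_normal(voxels.shape)
        voxels = voxels + session.noise_sigma * noise
    vol[session.mask] = voxels
    return vol


# ---------------------------------------------------------------------------
# conventional comparator arm
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConventionalBias:
    """Systematic offsets of the conventional arm relative to ground truth."""

    thickness_bias_mm: float = 0.17  # conventional cortex measured thicker
    volume_bias_frac: float = 0.03
    thickness_noise_sd_mm: float = 0.0
    volume_noise_sd_frac: float = 0.0


def conventional_arm(
    phantom: Phantom,
    bias: ConventionalBias | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Morphometry measurements of the conventional (reference) acquisition.

    Ground-truth volumes and cortical thickness of the phantom, shifted by a
    systematic bias and perturbed by seeded Gaussian measurement noise.
    Returns tidy rows (region_id, region_name, metric, value).
    """
    from .regions import region_volumes, shell_thickness

    bias = bias or ConventionalBias()
    rng = np.random.default_rng(seed)
    vols = region_volumes(phantom.labels, phantom.voxel_mm)
    names = dict(zip(phantom.tissue_table.region_id, phantom.tissue_table.region_name))
    rows = []
    for r in vols.itertuples():
        v = r.volume_mm3 * (1.0 + bias.volume_bias_frac)
        if bias.volume_noise_sd_frac > 0:
            v *= 1.0 + rng.normal(0.0, bias.volume_noise_sd_frac)
        rows.append((r.region_id, names.get(r.region_id, str(r.region_id)), "volume_mm3", v))
    th = shell_thickness(phantom.labels == CORTICAL_LABEL, phantom.voxel_mm)
    th = th + bias.thickness_bias_mm + rng.normal(0.0, bias.thickness_noise_sd_mm) * (
        1.0 if bias.thickness_noise_sd_mm > 0 else 0.0
    )
    rows.append((CORTICAL_LABEL, names.get(CORTICAL_LABEL, "cortical_gm"), "thickness_mm", th))
    return pd.DataFrame(rows, columns=["region_id", "region_name", "metric", "value"])
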