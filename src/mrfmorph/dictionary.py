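"""MRF dictionary: the (T1, T2) grid, simulated atoms, and SVD compression.

A dictionary atom is the unit-norm simulated signal evolution of one (T1, T2)
combination under a given schedule, retaining the second schedule repetition
(pseudo-steady state).  Compression projects atoms onto the leading temporal
left singular vectors of the atom matrix; matching in the subspace uses the
renormalized projected atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .epg import simulate_many
from .schedule import AcquisitionSchedule

__all__ = [
    "RelaxationGrid",
    "Dictionary",
    "CompressedDictionary",
    "build_grid",
    "build_dictionary",
    "compress",
    "save_dictionary",
    "load_dictionary",
    "DEFAULT_T1_RANGES_MS",
    "DEFAULT_T2_RANGES_MS",
]

# piecewise (start, stop, step) in ms, endpoints inclusive, shared endpoints
# deduplicated: the standard brain dictionary axes
DEFAULT_T1_RANGES_MS: tuple[tuple[float, float, float], ...] = (
    (10, 100, 10),
    (100, 1000, 20),
    (1000, 2000, 50),
    (2000, 6000, 100),
)
DEFAULT_T2_RANGES_MS: tuple[tuple[float, float, float], ...] = (
    (2, 100, 2),
    (100, 150, 5),
    (160, 300, 10),
    (300, 800, 50),
    (800, 1600, 100),
    (1600, 3000, 200),
)


def _expand_ranges(ranges) -> np.ndarray:
    vals: list[float] = []
    prev_stop = -np.inf
    for start, stop, step in ranges:
        if start <= 0 or stop < start or step <= 0:
            raise ValueError(f"invalid range ({start}, {stop}, {step})")
        if start < prev_stop:
            raise ValueError("ranges must be ordered and non-overlapping")
        n = int(round((stop - start) / step))
        vals.extend(start + step * np.arange(n + 1))
        prev_stop = stop
    out = np.unique(np.round(np.asarray(vals, dtype=float), 9))
    return out


@dataclass(frozen=True)
class RelaxationGrid:
    """Ascending, deduplicated T1 and T2 axes of the dictionary (ms)."""

    t1_values_ms: np.ndarray
    t2_values_ms: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t1_values_ms", "t2_values_ms"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.ndim != 1 or v.size == 0:
                raise ValueError(f"{name} must be a non-empty 1-D array")
            if np.any(v <= 0) or np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} must be positive and strictly increasing")

    @property
    def n_combinations(self) -> int:
        return int(self.t1_values_ms.size * self.t2_values_ms.size)

    def pairs(self, drop_t2_gt_t1: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """All (T1, T2) combinations, T2 fastest; optionally drop T2 > T1."""
        t1 = np.repeat(self.t1_values_ms, self.t2_values_ms.size)
        t2 = np.tile(self.t2_values_ms, self.t1_values_ms.size)
        if drop_t2_gt_t1:
            keep = t2 <= t1
            t1, t2 = t1[keep], t2[keep]
        return t1, t2


def build_grid(
    t1_ranges=DEFAULT_T1_RANGES_MS,
    t2_ranges=DEFAULT_T2_RANGES_MS,
) -> RelaxationGrid:
    """Expand the piecewise (start, stop, step) ranges into dictionary axes.

    Defaults give 115 T1 values (10 ms – 6 s) and 100 T2 values (2 ms – 3 s),
    endpoints inclusive and boundary duplicates removed, hence 11,500
    combinations.
    """
    return RelaxationGrid(_expand_ranges(t1_ranges), _expand_ranges(t2_ranges))


def decimate_grid(grid: RelaxationGrid, every: int) -> RelaxationGrid:
    """Keep every ``every``-th grid point on both axes (desk-scale runs)."""
    if every < 1:
        raise ValueError("every must be >= 1")
    return RelaxationGrid(grid.t1_values_ms[::every], grid.t2_values_ms[::every])


@dataclass(frozen=True)
class Dictionary:
    """Unit-norm simulated signal evolutions indexed by (T1, T2)."""

    atoms: np.ndarray  # (n_atoms, n_pulses), complex, rows unit L2 norm
    t1_lookup_ms: np.ndarray
    t2_lookup_ms: np.ndarray
    schedule_fingerprint: str
    grid: RelaxationGrid | None = None

    subspace_rank: int = 0  # 0 => uncompressed

    def __post_init__(self) -> None:
        if self.atoms.shape[0] != self.t1_lookup_ms.size or (
            self.t1_lookup_ms.size != self.t2_lookup_ms.size
        ):
            raise ValueError("lookup length must equal atom count")

    @property
    def n_atoms(self) -> int:
        return int(self.atoms.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.atoms.shape[1])


@dataclass(frozen=True)
class CompressedDictionary(Dictionary):
    """Dictionary projected on a rank-r temporal subspace.

    ``atoms`` holds the renormalized projected coefficients (n_atoms x r);
    ``basis`` the orthonormal temporal basis (n_pulses x r).  ``project``
    maps measured time-courses into the subspace.
    """

    basis: np.ndarray = field(default=None)  # type: ignore[assignment]
    projection_norms: np.ndarray = field(default=None)  # type: ignore[assignment]

    def project(self, signals: np.ndarray) -> np.ndarray:
        """Project time-domain signals (..., n_pulses) onto the subspace."""
        return signals @ np.conj(self.basis)


def build_dictionary(
    grid: RelaxationGrid,
    schedule: AcquisitionSchedule,
    n_iterations: int = 2,
    drop_t2_gt_t1: bool = False,
    batch_size: int = 2000,
    **sim_kwargs,
) -> Dictionary:
    """Simulate and L2-normalize one atom per (T1, T2) combination.

    Atoms are the second-repetition EPG signals; simulation runs in batches
    to bound memory.  Deterministic: two builds from identical inputs are
    bitwise identical.
    """
    t1, t2 = grid.pairs(drop_t2_gt_t1=drop_t2_gt_t1)
    atoms = np.empty((t1.size, schedule.n_pulses), dtype=complex)
    for lo in range(0, t1.size, batch_size):
        hi = min(lo + batch_size, t1.size)
        try:
            atoms[lo:hi] = simulate_many(
                schedule, t1[lo:hi], t2[lo:hi], n_iterations, **sim_kwargs
            )
        except Exception as exc:  # identify the offending combinations
            raise RuntimeError(
                f"simulation failed for (T1, T2) batch "
                f"[{t1[lo]}..{t1[hi - 1]}] x [{t2[lo]}..{t2[hi - 1]}] ms"
            ) from exc
    norms = np.linalg.norm(atoms, axis=1, keepdims=True)
    if np.any(norms == 0):
        bad = np.flatnonzero(norms[:, 0] == 0)[0]
        raise RuntimeError(f"zero-signal atom at (T1={t1[bad]}, T2={t2[bad]}) ms")
    atoms /= norms
    return Dictionary(
        atoms=atoms,
        t1_lookup_ms=t1,
        t2_lookup_ms=t2,
        schedule_fingerprint=schedule.fingerprint(),
        grid=grid,
    )


def compress(dictionary: Dictionary, rank: int = 10) -> CompressedDictionary:
    """Project the dictionary onto its leading temporal singular subspace.

    The basis is the first ``rank`` right singular vectors of the atom
    matrix (temporal side); projected atoms are renormalized so that
    subspace matching remains a normalized inner-product search.
    """
    if dictionary.subspace_rank:
        raise ValueError("dictionary is already compressed")
    max_rank = min(dictionary.n_atoms, dictionary.n_samples)
    if not (1 <= rank <= max_rank):
        raise ValueError(f"rank must be in [1, {max_rank}]")
    # temporal basis: rows of Vh span the signal (time) space
    _, _, vh = np.linalg.svd(dictionary.atoms, full_matrices=False)
    basis = np.ascontiguousarray(vh[:rank].conj().T)  # (n_pulses, rank)
    projected = dictionary.atoms @ np.conj(basis)
    norms = np.linalg.norm(projected, axis=1, keepdims=True)
    # an atom orthogonal to the subspace keeps zero coefficients
    safe = np.where(norms == 0, 1.0, norms)
    return CompressedDictionary(
        atoms=projected / safe,
        t1_lookup_ms=dictionary.t1_lookup_ms,
        t2_lookup_ms=dictionary.t2_lookup_ms,
        schedule_fingerprint=dictionary.schedule_fingerprint,
        grid=dictionary.grid,
        subspace_rank=rank,
        basis=basis,
        projection_norms=norms[:, 0],
    )


# ---------------------------------------------------------------------------
# HDF5 store
# ---------------------------------------------------------------------------

def save_dictionary(
    dictionary: Dictionary, path: str | Path, schedule: AcquisitionSchedule | None = None
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("atoms", data=dictionary.atoms)
        f.create_dataset("t1_lookup", data=dictionary.t1_lookup_ms)
        f.create_dataset("t2_lookup", data=dictionary.t2_lookup_ms)
        f.attrs["schedule_fingerprint"] = dictionary.schedule_fingerprint
        f.attrs["subspace_rank"] = dictionary.subspace_rank
        if dictionary.grid is not None:
            f.create_dataset("grid_t1", data=dictionary.grid.t1_values_ms)
            f.create_dataset("grid_t2", data=dictionary.grid.t2_values_ms)
        if isinstance(dictionary, CompressedDictionary):
            f.create_dataset("basis", data=dictionary.basis)
            f.create_dataset("projection_norms", data=dictionary.projection_norms)
        if schedule is not None:
            g = f.create_group("schedule")
            g.create_dataset("flip_angles_deg", data=schedule.flip_angles_deg)
            g.attrs.update(
                tr_ms=schedule.tr_ms,
                te_ms=schedule.te_ms,
                n_segments=schedule.n_segments,
                inversion=schedule.inversion,
                spoiler_dephasing_cycles=schedule.spoiler_dephasing_cycles,
            )


def load_dictionary(path: str | Path) -> Dictionary:
    with h5py.File(path, "r") as f:
        grid = None
        if "grid_t1" in f:
            grid = RelaxationGrid(f["grid_t1"][:], f["grid_t2"][:])
        common = dict(
            t1_lookup_ms=f["t1_lookup"][:],
            t2_lookup_ms=f["t2_lookup"][:],
            schedule_fingerprint=str(f.attrs["schedule_fingerprint"]),
            grid=grid,
        )
        if int(f.attrs.get("subspace_rank", 0)):
            return CompressedDictionary(
                atoms=f["atoms"][:],
                subspace_rank=int(f.attrs["subspace_rank"]),
                basis=f["basis"][:],
                projection_norms=f["projection_norms"][:],
                **common,
            )
        return Dictionary(atoms=f["atoms"][:], **common)


def load_schedule_from_store(path: str | Path) -> AcquisitionSchedule:
    with h5py.File(path, "r") as f:
        g = f["schedule"]
        return AcquisitionSchedule(
            flip_angles_deg=g["flip_angles_deg"][:],
            tr_ms=float(g.attrs["tr_ms"]),
            te_ms=float(g.attrs["te_ms"]),
            n_segments=int(g.attrs["n_segments"]),
            inversion=bool(g.attrs["inversion"]),
            spoiler_dephasing_cycles=int(g.attrs["spoiler_dephasing_cycles"]),
        )
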