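"""Deterministic streamline tractography over diffusion tensor volumes.

Implements fixed-step principal-eigenvector tracking with the standard
stopping criteria used for skeletal muscle fascicle reconstruction
(fractional anisotropy threshold, inter-segment turn angle, maximum tract
length), anatomically constrained post-processing that clips tracts at the
muscle boundary, and extraction of the architecture summary a Hill-type
model needs: mean fascicle length, pennation angle and muscle volume.

Coordinates are millimetres throughout.  Voxel (i, j, k) has its centre at
``origin + (i + 0.5, j + 0.5, k + 0.5) * spacing`` so that a volume of
shape ``n`` spans ``[origin, origin + n * spacing)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "TensorVolume",
    "TractographyParams",
    "FibreTractSet",
    "ArchitectureSummary",
    "compute_fa",
    "track_fibres",
    "constrain_tracts",
    "summarize_architecture",
    "save_tensor_nifti",
    "load_tensor_nifti",
    "save_mask_nifti",
    "load_mask_nifti",
]

# upper-triangle component order used for the 6-channel NIfTI representation
_UT = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


@dataclass
class TensorVolume:
    """Voxel grid of symmetric 3x3 diffusion tensors.

    grid has shape (nx, ny, nz, 3, 3); spacing and origin are mm triples.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 5 or self.grid.shape[3:] != (3, 3):
            raise ValueError("tensor grid must have shape (nx, ny, nz, 3, 3)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if not np.allclose(self.grid, np.swapaxes(self.grid, 3, 4), atol=1e-9):
            raise ValueError("tensors must be symmetric")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape[:3]

    def voxel_index(self, point: np.ndarray) -> tuple[int, int, int] | None:
        """Nearest-voxel index for a world point, or None outside the volume."""
        idx = (np.asarray(point) - np.asarray(self.origin)) / np.asarray(self.spacing)
        ijk = np.floor(idx).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= np.asarray(self.shape)):
            return None
        return tuple(ijk)


@dataclass
class TractographyParams:
    """Stopping criteria and seeding configuration for streamline tracking."""

    step_size: float = 1.0            # mm
    fa_threshold: float = 0.5         # stop when FA <= threshold
    max_turn_angle: float = 30.0      # deg; stop when inter-segment angle exceeds it
    max_tract_length: float = 200.0   # mm, set per muscle from belly length
    n_seeds: int = 5000
    rng_seed: int = 0
    min_tract_length: float | None = None  # default 5 * step_size

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if not 0 < self.fa_threshold < 1:
            raise ValueError("fa_threshold must lie in (0, 1)")
        if not 0 < self.max_turn_angle < 90:
            raise ValueError("max_turn_angle must lie in (0, 90) degrees")
        if self.max_tract_length <= 0:
            raise ValueError("max_tract_length must be positive")
        if self.min_tract_length is None:
            self.min_tract_length = 5.0 * self.step_size


@dataclass
class FibreTractSet:
    """A set of streamlines, each an (n_points, 3) polyline in mm."""

    tracts: list[np.ndarray]
    seeds: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    @property
    def lengths(self) -> np.ndarray:
        return np.array([polyline_length(t) for t in self.tracts])

    def __len__(self) -> int:
        return len(self.tracts)


@dataclass
class ArchitectureSummary:
    """Per-muscle architecture extracted from constrained tracts."""

    Lf_raw: float       # mm, mean constrained tract length
    pennation: float    # degrees
    n_retained: int
    Vm: float           # mm^3, mask voxel count x voxel volume


def polyline_length(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def compute_fa(tensor: np.ndarray) -> float:
    """Fractional anisotropy of a symmetric 3x3 tensor.

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda|| over the
    eigenvalues; the zero tensor maps to 0 by convention.  Eigenvalues that
    come out slightly negative (numerical noise) are clamped to zero with a
    warning.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3):
        raise ValueError("tensor must be 3x3")
    if not np.allclose(tensor, tensor.T, atol=1e-8):
        raise ValueError("tensor must be symmetric")
    lam = np.linalg.eigvalsh(tensor)
    if np.any(lam < -1e-10):
        warnings.warn("negative tensor eigenvalues clamped to zero", stacklevel=2)
    lam = np.clip(lam, 0.0, None)
    norm = np.linalg.norm(lam)
    if norm == 0.0:
        return 0.0
    return float(np.sqrt(1.5) * np.linalg.norm(lam - lam.mean()) / norm)


def _fa_field(grid: np.ndarray) -> np.ndarray:
    """Vectorised FA over a (..., 3, 3) tensor array."""
    lam = np.linalg.eigvalsh(grid)
    lam = np.clip(lam, 0.0, None)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    out = np.zeros(num.shape)
    np.divide(np.sqrt(1.5) * num, den, out=out, where=den > 0)
    return out


def _principal_field(grid: np.ndarray) -> np.ndarray:
    """Principal eigenvector per voxel, shape (..., 3)."""
    _, vecs = np.linalg.eigh(grid)
    return vecs[..., :, 2]  # eigh sorts ascending


def track_fibres(vol: TensorVolume, mask: np.ndarray, params: TractographyParams) -> FibreTractSet:
    """Deterministic bidirectional streamline tracking from seeds inside a mask.

    From each seed the principal-eigenvector field is integrated with
    fixed-step Euler steps (nearest-neighbour tensor lookup), sign-aligning
    each step with the previous direction.  A direction terminates when FA
    drops to or below the threshold, the turn between successive segments
    exceeds the maximum angle, the point leaves the volume, or the
    cumulative tract length would exceed the maximum.  Fully deterministic
    for a fixed ``rng_seed``.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != vol.shape:
        raise ValueError("mask and tensor volume must share a grid")
    if not mask.any():
        raise ValueError("mask is empty")

    fa = _fa_field(vol.grid)
    evec = _principal_field(vol.grid)

    rng = np.random.default_rng(params.rng_seed)
    seeds = _sample_seeds(mask, vol, params.n_seeds, rng)

    cos_limit = np.cos(np.radians(params.max_turn_angle))

    tracts: list[np.ndarray] = []
    for seed in seeds:
        # the length budget covers the whole tract (a fascicle cannot exceed
        # the muscle belly length), so the backward pass gets what the
        # forward pass left over
        fwd = _integrate(seed, +1, vol, fa, evec, params, cos_limit,
                         params.max_tract_length)
        remaining = params.max_tract_length - params.step_size * (len(fwd) - 1)
        bwd = _integrate(seed, -1, vol, fa, evec, params, cos_limit, remaining)
        tract = np.vstack([bwd[::-1], fwd[1:]]) if len(bwd) > 1 else fwd
        tracts.append(tract)
    return FibreTractSet(tracts=tracts, seeds=seeds)


def _sample_seeds(mask: np.ndarray, vol: TensorVolume, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform rejection sampling of seed points within the mask volume."""
    lo = np.asarray(vol.origin)
    hi = lo + np.asarray(vol.shape) * np.asarray(vol.spacing)
    seeds = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(lo, hi, size=(4 * (n - got), 3))
        idx = np.floor((cand - lo) / np.asarray(vol.spacing)).astype(int)
        ok = mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        take = cand[ok][: n - got]
        seeds[got : got + len(take)] = take
        got += len(take)
    return seeds


def _integrate(seed, sign, vol, fa, evec, params, cos_limit, budget) -> np.ndarray:
    """One tracking direction; the violating point is never included."""
    pos = np.asarray(seed, dtype=float)
    points = [pos]
    prev_dir = None
    length = 0.0
    ijk = vol.voxel_index(pos)
    if ijk is None or fa[ijk] <= params.fa_threshold:
        return np.asarray(points)
    while length + params.step_size <= budget + 1e-12:
        d = evec[vol.voxel_index(pos)]
        if prev_dir is None:
            d = d * sign
        elif float(d @ prev_dir) < 0:
            d = -d
        if prev_dir is not None and float(d @ prev_dir) < cos_limit:
            break
        cand = pos + d * params.step_size
        cijk = vol.voxel_index(cand)
        if cijk is None or fa[cijk] <= params.fa_threshold:
            break
        pos = cand
        points.append(pos)
        length += params.step_size
        prev_dir = d
    return np.asarray(points)


def constrain_tracts(tracts: FibreTractSet, mask: np.ndarray, vol: TensorVolume,
                     min_tract_length: float) -> FibreTractSet:
    """Anatomically constrained post-processing.

    Each tract is clipped at the first mask-boundary crossing on either side
    of the seed, so no retained point lies outside the muscle; tracts
    shorter than ``min_tract_length`` are then discarded.
    """
    mask = np.asarray(mask).astype(bool)
    kept: list[np.ndarray] = []
    for tract in tracts.tracts:
        inside = np.array([_in_mask(p, mask, vol) for p in tract])
        if not inside.any():
            continue
        # longest contiguous inside run containing the tract midpoint region:
        # take the run that contains the seed (middle of the polyline)
        runs = _runs(inside)
        mid = len(tract) // 2
        run = next((r for r in runs if r[0] <= mid < r[1]), max(runs, key=lambda r: r[1] - r[0]))
        clipped = tract[run[0] : run[1]]
        if polyline_length(clipped) >= min_tract_length:
            kept.append(clipped)
    if not kept:
        warnings.warn("no tracts survived anatomical constraint", stacklevel=2)
    return FibreTractSet(tracts=kept, seeds=tracts.seeds)


def _in_mask(point: np.ndarray, mask: np.ndarray, vol: TensorVolume) -> bool:
    ijk = vol.voxel_index(point)
    return ijk is not None and bool(mask[ijk])


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index ranges of consecutive True values."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(flags)))
    return runs


def summarize_architecture(tracts: FibreTractSet, line_of_action: np.ndarray,
                           mask: np.ndarray, spacing: tuple[float, float, float]) -> ArchitectureSummary:
    """Fascicle length, pennation angle and volume from constrained tracts.

    Fascicle length is the mean polyline arc length; pennation is the mean
    angle between each tract's end-to-end chord and the muscle's line of
    action; volume is the voxel count of the mask times the voxel volume.
    """
    if len(tracts) == 0:
        raise ValueError("cannot summarise architecture from zero retained tracts")
    loa = np.asarray(line_of_action, dtype=float)
    loa = loa / np.linalg.norm(loa)
    angles = []
    for tract in tracts.tracts:
        chord = tract[-1] - tract[0]
        norm = np.linalg.norm(chord)
        if norm == 0:
            continue
        cosang = abs(float(chord @ loa)) / norm
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    mask = np.asarray(mask).astype(bool)
    vm = float(mask.sum()) * float(np.prod(spacing))
    return ArchitectureSummary(
        Lf_raw=float(np.mean(tracts.lengths)),
        pennation=float(np.mean(angles)),
        n_retained=len(tracts),
        Vm=vm,
    )


# --- NIfTI I/O -------------------------------------------------------------

def save_tensor_nifti(vol: TensorVolume, path: str) -> None:
    """Write a tensor volume as a 6-component upper-triangle NIfTI."""
    data = np.stack([vol.grid[..., i, j] for i, j in _UT], axis=-1)
    affine = np.diag([*vol.spacing, 1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(data.astype(np.float64), affine), path)


def load_tensor_nifti(path: str) -> TensorVolume:
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError("expected a 4D NIfTI with 6 tensor components")
    grid = np.zeros(data.shape[:3] + (3, 3))
    for c, (i, j) in enumerate(_UT):
        grid[..., i, j] = data[..., c]
        grid[..., j, i] = data[..., c]
    affine = img.affine
    spacing = tuple(float(affine[i, i]) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    return TensorVolume(grid=grid, spacing=spacing, origin=origin)


def save_mask_nifti(mask: np.ndarray, spacing, origin, path: str) -> None:
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), path)


def load_mask_nifti(path: str) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj) > 0
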