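"""Locus coeruleus intensity quantification from a dedicated MRI slab.

The signal is summarized in three steps: per-slice contrast-ratio
normalization against a pontine reference mask, a deterministic multi-restart
search for the brightest contiguous five-voxel set inside the LC mask, and
sign inversion so that higher values indicate poorer integrity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import BrainVolume
from .exceptions import ExtractionError, NormalizationError

__all__ = [
    "LcIntensityRecord",
    "normalize_to_reference",
    "extract_lc_intensity",
    "invert_and_average",
    "neighbor_offsets",
]

SLICE_AXIS = 2  # slab slices are stacked along the third axis


@dataclass
class LcIntensityRecord:
    subject_id: str
    timepoint: str  # "baseline" | "followup"
    intensity_left: float
    intensity_right: float
    intensity_mean: float
    intensity_r: float


def normalize_to_reference(slab: BrainVolume, ref_mask: BrainVolume,
                           lc_mask: BrainVolume | None = None,
                           slice_axis: int = SLICE_AXIS) -> BrainVolume:
    """Per-slice contrast-ratio normalization.

    Each slice's voxels become ``(I - mean_ref) / mean_ref`` where
    ``mean_ref`` is the mean of that slice's reference-mask voxels, so the
    reference voxels of every normalized slice average to zero. Slices with
    no reference voxels are filled with NaN, unless they contain LC-mask
    voxels, in which case a :class:`NormalizationError` names the slice.
    """
    slab.check_compatible(ref_mask)
    ref = ref_mask.require_mask()
    need = None
    if lc_mask is not None:
        slab.check_compatible(lc_mask)
        need = lc_mask.require_mask()

    out = np.full(slab.shape, np.nan, dtype=float)
    n_slices = slab.shape[slice_axis]
    for s in range(n_slices):
        idx = [slice(None)] * 3
        idx[slice_axis] = s
        idx = tuple(idx)
        ref_slice = ref[idx]
        if not ref_slice.any():
            if need is not None and need[idx].any():
                raise NormalizationError(
                    f"slice {s} contains LC voxels but no reference voxels",
                    slice_index=s,
                )
            continue
        mean_ref = float(slab.data[idx][ref_slice].mean())
        if mean_ref == 0:
            raise NormalizationError(
                f"slice {s}: reference mean is zero", slice_index=s
            )
        out[idx] = (slab.data[idx] - mean_ref) / mean_ref
    return slab.with_data(out)


def neighbor_offsets(mode: str = "3d") -> np.ndarray:
    """26-connected offsets (``"3d"``) or in-plane 8-connected (``"2d"``)."""
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if di == dj == dk == 0:
                    continue
                if mode == "2d" and dk != 0:
                    continue
                offs.append((di, dj, dk))
    return np.array(offs, dtype=int)


def _greedy_from_seed(seed: int, values: np.ndarray, shape: tuple,
                      in_mask: np.ndarray, offsets: np.ndarray,
                      n_voxels: int) -> tuple[float, frozenset] | None:
    """Grow a connected set from one seed by repeatedly adding the brightest
    in-mask neighbor (ties broken by ascending linear index)."""
    chosen = {seed}
    while len(chosen) < n_voxels:
        best = None
        for lin in chosen:
            ijk = np.unravel_index(lin, shape)
            cand = np.asarray(ijk) + offsets
            ok = np.all((cand >= 0) & (cand < np.asarray(shape)), axis=1)
            for c in cand[ok]:
                lin_c = int(np.ravel_multi_index(c, shape))
                if lin_c in chosen or not in_mask[lin_c]:
                    continue
                key = (-values[lin_c], lin_c)
                if best is None or key < best[0]:
                    best = (key, lin_c)
        if best is None:
            return None  # seed's component smaller than n_voxels
        chosen.add(best[1])
    mean = float(np.mean([values[i] for i in chosen]))
    return mean, frozenset(chosen)


def _neighbors_of(lin: int, shape: tuple, in_mask: np.ndarray,
                  offsets: np.ndarray) -> list[int]:
    ijk = np.unravel_index(lin, shape)
    cand = np.asarray(ijk) + offsets
    ok = np.all((cand >= 0) & (cand < np.asarray(shape)), axis=1)
    out = []
    for c in cand[ok]:
        lin_c = int(np.ravel_multi_index(c, shape))
        if in_mask[lin_c]:
            out.append(lin_c)
    return out


def _connected(lins: set, shape: tuple, offsets: np.ndarray) -> bool:
    lins = set(lins)
    start = next(iter(lins))
    seen = {start}
    frontier = [start]
    ones = np.ones(int(np.prod(shape)), dtype=bool)
    while frontier:
        cur = frontier.pop()
        for nb in _neighbors_of(cur, shape, ones, offsets):
            if nb in lins and nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    return len(seen) == len(lins)


def _refine_by_swaps(chosen: frozenset, values: np.ndarray, shape: tuple,
                     in_mask: np.ndarray, offsets: np.ndarray) -> tuple:
    """Deterministic steepest-ascent 1-swap refinement of a connected set."""
    current = set(chosen)
    mean = float(np.mean([values[i] for i in current]))
    improved = True
    while improved:
        improved = False
        border = set()
        for lin in current:
            border.update(_neighbors_of(lin, shape, in_mask, offsets))
        border -= current
        best = None
        for add in sorted(border):
            for drop in sorted(current):
                trial = (current - {drop}) | {add}
                trial_mean = float(np.mean([values[i] for i in trial]))
                if trial_mean <= mean + 1e-15:
                    continue
                if not _connected(trial, shape, offsets):
                    continue
                key = (-trial_mean, tuple(sorted(trial)))
                if best is None or key < best[0]:
                    best = (key, trial, trial_mean)
        if best is not None:
            current, mean = best[1], best[2]
            improved = True
    return mean, frozenset(current)


def extract_lc_intensity(norm_slab: BrainVolume, lc_mask: BrainVolume,
                         n_voxels: int = 5, n_seeds: int = 30,
                         connectivity: str = "3d",
                         return_voxels: bool = False):
    """Mean of the brightest contiguous ``n_voxels`` in-mask voxels.

    Runs ``n_seeds`` deterministic greedy searches seeded at the brightest
    in-mask voxels (ties by ascending linear index), each followed by a
    steepest-ascent one-voxel-swap refinement, and returns the best mean
    found. Connectivity is 26-connected in 3-D by default; ``"2d"``
    restricts contiguity to within-slice.
    """
    norm_slab.check_compatible(lc_mask)
    mask = lc_mask.require_mask()
    flat_vals = norm_slab.data.ravel()
    in_mask = mask.ravel()
    lin_idx = np.flatnonzero(in_mask)
    if lin_idx.size < n_voxels:
        raise ExtractionError(
            f"LC mask has {lin_idx.size} voxels; need >= {n_voxels}"
        )
    if np.isnan(flat_vals[lin_idx]).any():
        raise ExtractionError("normalized slab is NaN inside the LC mask")

    order = np.lexsort((lin_idx, -flat_vals[lin_idx]))
    seeds = lin_idx[order][:n_seeds]
    offsets = neighbor_offsets(connectivity)
    shape = norm_slab.shape

    best_mean = -np.inf
    best_set: frozenset | None = None
    for seed in seeds:
        res = _greedy_from_seed(int(seed), flat_vals, shape, in_mask,
                                offsets, n_voxels)
        if res is None:
            continue
        mean, chosen = _refine_by_swaps(res[1], flat_vals, shape, in_mask,
                                        offsets)
        if mean > best_mean:
            best_mean, best_set = mean, chosen
    if best_set is None:
        raise ExtractionError(
            "no connected set of the requested size exists in the mask"
        )
    if return_voxels:
        return best_mean, sorted(best_set)
    return best_mean


def invert_and_average(left: float, right: float) -> dict[str, float]:
    """Average hemispheres, then invert so higher = worse integrity."""
    mean = (left + right) / 2.0
    return {
        "intensity_left": float(left),
        "intensity_right": float(right),
        "intensity_mean": float(mean),
        "intensity_r": float(-mean),
    }
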