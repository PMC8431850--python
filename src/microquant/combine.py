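"""Combining two independently segmented object sets into one label image.

Segmentation workflows often define objects in stages — e.g. segment bright
nuclei first, mask them out, then segment dimmer ones — and the two resulting
label images must be merged into a single object set before measurement.
Pixels claimed by objects from both sets (the *disputed region*) need a
resolution strategy:

``merge``
    Every pixel of both sets is kept; each disputed pixel is handed to the
    nearest object of the *initial* set (Euclidean distance to that object's
    undisputed pixels), then touching objects that originate from different
    input sets are fused into one object.
``preserve``
    Initial objects keep all their pixels; addition objects contribute only
    the pixels falling outside the initial foreground. Addition objects left
    with nothing are dropped.
``discard``
    Initial objects are kept intact; an addition object is added whole only
    if it overlaps the initial foreground by zero pixels.
``segment``
    Both foregrounds are kept and the disputed region is re-segmented by
    seeded nearest-seed growth, each object's undisputed pixel set acting as
    its seed. Objects with no undisputed pixels have no seed and are dropped.

Determinism: nearest-object/nearest-seed ties are broken by source set
(initial before addition), then lower original object id; output ids are
renumbered sequentially from 1 in (source set, original id) order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import DimensionError, LabelImage

STRATEGIES = ("merge", "preserve", "discard", "segment")


@dataclass(frozen=True)
class CombineReport:
    """Audit counts for one combination run."""

    n_initial: int
    n_added: int
    n_dropped: int
    n_disputed_pixels: int
    strategy: str


def overlap_mask(initial: LabelImage, addition: LabelImage) -> np.ndarray:
    """Boolean grid of disputed pixels: foreground in *both* inputs."""
    if initial.shape != addition.shape:
        raise DimensionError(
            f"shape mismatch: {initial.shape} vs {addition.shape}"
        )
    return (initial.labels > 0) & (addition.labels > 0)


def _structure(ndim: int, connectivity: str) -> np.ndarray:
    if connectivity == "full":
        return ndimage.generate_binary_structure(ndim, ndim)
    if connectivity == "face":
        return ndimage.generate_binary_structure(ndim, 1)
    raise ValueError(f"unknown connectivity {connectivity!r} (use 'full' or 'face')")


def _nearest_seed_assignment(
    seeds: list[np.ndarray], target: np.ndarray
) -> np.ndarray:
    """For each True pixel of ``target``, index of the nearest seed mask.

    ``seeds`` is an ordered list of boolean masks; distance is exact Euclidean
    (distance transform per seed). Ties go to the earliest seed in the list,
    which encodes the (source set, original id) priority.
    """
    n_target = int(target.sum())
    dists = np.empty((len(seeds), n_target), dtype=np.float64)
    for i, seed in enumerate(seeds):
        dists[i] = ndimage.distance_transform_edt(~seed)[target]
    # round to kill float jitter in sqrt so genuine ties break by seed order
    return np.argmin(np.round(dists, 9), axis=0)


def combine_objects(
    initial: LabelImage,
    addition: LabelImage,
    strategy: str = "merge",
    connectivity: str = "full",
) -> tuple[LabelImage, CombineReport]:
    """Merge two object sets into one label image.

    Returns the combined :class:`LabelImage` (ids renumbered sequentially
    from 1) and a :class:`CombineReport` with audit counts. ``n_added``
    counts addition objects contributing at least one pixel before any
    merge-fusion; ``n_dropped`` counts addition objects eliminated outright
    by the strategy (fully covered / overlapping / seedless).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    disputed = overlap_mask(initial, addition)  # also validates shapes
    struct = _structure(initial.ndim, connectivity)

    lab1 = initial.labels
    lab2 = addition.labels
    ids1 = initial.ids
    ids2 = addition.ids

    # Sequential output ids: initial objects first (ascending original id),
    # then surviving addition objects. ``sources`` tracks provenance for the
    # merge-fusion rule.
    out = np.zeros(lab1.shape, dtype=np.int32)
    new_id_1 = {int(i): k + 1 for k, i in enumerate(ids1)}
    for orig, new in new_id_1.items():
        out[lab1 == orig] = new
    next_id = len(ids1) + 1

    n_dropped = 0
    n_added = 0

    if strategy == "discard":
        for orig in ids2:
            obj = lab2 == orig
            if (obj & disputed).any():
                n_dropped += 1
            else:
                out[obj] = next_id
                next_id += 1
                n_added += 1
        sources = None
    elif strategy == "preserve":
        for orig in ids2:
            contrib = (lab2 == orig) & ~disputed
            if contrib.any():
                out[contrib] = next_id
                next_id += 1
                n_added += 1
            else:
                n_dropped += 1
        sources = None
    elif strategy == "merge":
        # start from preserve's assignment
        add_new_ids = []
        for orig in ids2:
            contrib = (lab2 == orig) & ~disputed
            if contrib.any():
                out[contrib] = next_id
                add_new_ids.append(next_id)
                next_id += 1
                n_added += 1
            else:
                n_dropped += 1
        # reassign disputed pixels to the nearest initial object's
        # undisputed pixels
        if disputed.any() and len(ids1):
            seeds = []
            seed_ids = []
            for orig in ids1:
                undisputed = (lab1 == orig) & ~disputed
                if undisputed.any():
                    seeds.append(undisputed)
                    seed_ids.append(new_id_1[int(orig)])
            if seeds:
                choice = _nearest_seed_assignment(seeds, disputed)
                out[disputed] = np.asarray(seed_ids, dtype=np.int32)[choice]
            # else: initial foreground is fully disputed; keep preserve's
            # assignment (each disputed pixel stays with its initial object)
        sources = {new: 0 for new in new_id_1.values()}
        sources.update({new: 1 for new in add_new_ids})
        out = _fuse_cross_source(out, sources, struct)
    else:  # segment
        # seeds: undisputed pixels per object, both sets; initial first
        seeds = []
        for orig in ids1:
            undisputed = (lab1 == orig) & ~disputed
            if undisputed.any():
                seeds.append((0, undisputed))
        kept_from_add = 0
        for orig in ids2:
            undisputed = (lab2 == orig) & ~disputed
            if undisputed.any():
                seeds.append((1, undisputed))
                kept_from_add += 1
            else:
                n_dropped += 1
        n_added = kept_from_add
        if not seeds:
            # fully disputed everywhere (e.g. identical foregrounds): no
            # object can claim territory by seed growth, so fall back to the
            # initial labeling to keep the union foreground covered
            out = lab1.copy()
        else:
            out = np.zeros(lab1.shape, dtype=np.int32)
            for k, (_src, seed) in enumerate(seeds):
                out[seed] = k + 1
            if disputed.any():
                choice = _nearest_seed_assignment([s for _, s in seeds], disputed)
                out[disputed] = (choice + 1).astype(np.int32)
        sources = None

    out = _renumber_sequential(out)
    report = CombineReport(
        n_initial=len(ids1),
        n_added=n_added,
        n_dropped=n_dropped,
        n_disputed_pixels=int(disputed.sum()),
        strategy=strategy,
    )
    return LabelImage(out), report


def _fuse_cross_source(
    out: np.ndarray, sources: dict[int, int], struct: np.ndarray
) -> np.ndarray:
    """Fuse output objects that touch and originate from different sets.

    Builds the adjacency graph of output objects under ``struct``; edges are
    kept only between objects from different source sets, and connected
    components of that graph become single objects. Two initial-set objects
    bridged by an addition-set object therefore fuse transitively, while two
    touching initial-set objects with no bridge stay separate.
    """
    edges = set()
    ndim = out.ndim
    for offset in np.argwhere(struct) - 1:
        if (offset == 0).all():
            continue
        src_sl = []
        dst_sl = []
        skip = False
        for d in range(ndim):
            o = int(offset[d])
            if o >= 0:
                src_sl.append(slice(0, out.shape[d] - o))
                dst_sl.append(slice(o, out.shape[d]))
            else:
                src_sl.append(slice(-o, out.shape[d]))
                dst_sl.append(slice(0, out.shape[d] + o))
            if out.shape[d] - abs(o) <= 0:
                skip = True
        if skip:
            continue
        a = out[tuple(src_sl)]
        b = out[tuple(dst_sl)]
        touching = (a > 0) & (b > 0) & (a != b)
        if touching.any():
            pairs = np.unique(
                np.stack([a[touching], b[touching]], axis=1), axis=0
            )
            for p, q in pairs:
                edges.add((int(min(p, q)), int(max(p, q))))

    # union-find over cross-source edges only
    parent = {i: i for i in sources}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p, q in edges:
        if sources.get(p) != sources.get(q):
            rp, rq = find(p), find(q)
            if rp != rq:
                parent[max(rp, rq)] = min(rp, rq)

    if all(find(i) == i for i in sources):
        return out
    mapping = np.zeros(max(sources) + 1, dtype=np.int32)
    for i in sources:
        mapping[i] = find(i)
    return mapping[out]


def _renumber_sequential(out: np.ndarray) -> np.ndarray:
    """Relabel to consecutive ids 1..n preserving ascending id order."""
    ids = np.unique(out)
    ids = ids[ids > 0]
    mapping = np.zeros((int(ids.max()) + 1) if ids.size else 1, dtype=np.int32)
    mapping[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return mapping[out]
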