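"""Canonical scalp layouts and the classical A-D microstate motifs.

Resting EEG microstate literature sorts templates into four canonical
classes: A and B are mirror-image diagonal gradients (left-posterior to
right-frontal and its left-right flip), C is an anterior-posterior
gradient, and D a fronto-central focal peak.  These motifs are generated
analytically on any 2-D head layout; they serve both as the generative
templates of the synthetic cohort and as the sorting reference of the
microstate pipeline.
"""

from __future__ import annotations

import numpy as np

__all__ = ["disk_layout", "canonical_templates", "unit_gfp", "average_reference"]


def average_reference(maps: np.ndarray) -> np.ndarray:
    """Remove the channel mean of each map (rows = maps)."""
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    return maps - maps.mean(axis=1, keepdims=True)


def unit_gfp(maps: np.ndarray) -> np.ndarray:
    """Average-reference and scale each map to unit global field power."""
    maps = average_reference(maps)
    gfp = maps.std(axis=1, keepdims=True)
    if np.any(gfp == 0):
        raise ValueError("cannot normalize an all-constant map to unit GFP")
    return maps / gfp


def disk_layout(n_channels: int) -> np.ndarray:
    """Left-right symmetric electrode layout on the unit disk.

    Channels are placed on concentric rings (a vertex electrode plus rings
    of even size), which guarantees that every channel has an exact mirror
    partner across the anterior-posterior axis.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels for a 2-D layout")
    pos = [(0.0, 0.0)]
    n_left = n_channels - 1
    # distribute remaining channels over rings of increasing radius
    n_rings = max(2, int(np.ceil(np.sqrt(n_left / 2))))
    base = n_left // n_rings
    sizes = []
    for i in range(n_rings):
        m = base + (1 if i < n_left % n_rings else 0)
        sizes.append(m + (m % 2))              # force even ring size
    # fix total after rounding up
    while sum(sizes) > n_left:
        j = int(np.argmax(sizes))
        sizes[j] -= 2
    while sum(sizes) < n_left:
        j = int(np.argmin(sizes))
        sizes[j] += 2
    sizes = [s for s in sizes if s > 0]
    for i, m in enumerate(sizes):
        r = (i + 1) / len(sizes)
        # angles symmetric about the y axis: pair theta and pi - theta
        ang = np.pi / 2 + np.pi * (2 * np.arange(m) + 1) / m
        for a in ang:
            pos.append((r * np.cos(a), r * np.sin(a)))
    pos = np.asarray(pos[:n_channels])
    return pos


def canonical_templates(n_channels: int,
                        positions: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Return (maps, positions): four unit-GFP canonical maps A-D.

    A: left-posterior to right-frontal diagonal gradient;
    B: the left-right mirror of A;
    C: anterior-posterior gradient;
    D: fronto-central focal peak (Gaussian bump ahead of the vertex).
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels to express the gradients")
    if positions is None:
        positions = disk_layout(n_channels)
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (n_channels, 2):
        raise ValueError("positions must be (n_channels, 2)")
    x, y = positions[:, 0], positions[:, 1]
    map_a = x + y
    map_b = -x + y
    map_c = -y
    map_d = np.exp(-(((x - 0.0) ** 2 + (y - 0.35) ** 2) / (2 * 0.35 ** 2)))
    maps = np.vstack([map_a, map_b, map_c, map_d])
    return unit_gfp(maps), positions
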