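"""Independent reference implementations used to check the package.

These deliberately avoid the library's own code paths: plain loops and
textbook algorithms, kept simple enough to verify by eye.
"""

from collections import deque

import numpy as np


def naive_slice_oracle(atlas, plane, out_shape):
    """Per-pixel loop recomputing each 3D point and sampling the volume."""
    ns, nt = out_shape
    out = np.zeros((ns, nt), dtype=atlas.annotation.dtype)
    shape = np.asarray(atlas.shape)
    for s in range(ns):
        for t in range(nt):
            point = plane.origin + plane.pixel_size_mm * (s * plane.u + t * plane.v)
            vox = point / np.asarray(atlas.voxel_size_mm) + np.asarray(atlas.bregma_voxel)
            idx = np.rint(vox).astype(int)
            if np.all((idx >= 0) & (idx < shape)):
                out[s, t] = atlas.annotation[tuple(idx)]
    return out


def bfs_flood_fill(image, seed_xy, tolerance, connectivity):
    """Breadth-first-search flood fill compared against the magic wand."""
    h, w = image.shape
    x0, y0 = seed_xy
    ref = float(image[y0, x0])
    neighbors = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        neighbors += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    mask = np.zeros((h, w), dtype=bool)
    queue = deque([(y0, x0)])
    mask[y0, x0] = True
    while queue:
        y, x = queue.popleft()
        for dy, dx in neighbors:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not mask[ny, nx]:
                if abs(float(image[ny, nx]) - ref) <= tolerance:
                    mask[ny, nx] = True
                    queue.append((ny, nx))
    return mask


def channel_count_oracle(traj, geometry, atlas):
    """Exhaustive per-channel enumeration of in-brain channel counts."""
    from histoatlas.atlas_core import sample_labels, stereotaxic_to_voxel

    counts = {}
    for i in range(geometry.n_channels):
        d_mm = (geometry.tip_length_um + geometry.first_channel_offset_um
                + i * geometry.channel_pitch_um) / 1000.0
        pos = traj.tip.as_xyz() - d_mm * traj.direction
        vox, _ = stereotaxic_to_voxel(pos[None, :], atlas)
        lab = int(sample_labels(atlas, vox)[0])
        if lab != 0:
            counts[lab] = counts.get(lab, 0) + 1
    return counts
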