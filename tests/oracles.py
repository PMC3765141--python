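"""Brute-force reference implementations used only by the tests.

Each function recomputes a pipeline operation by the most literal
possible method (per-cell loops, all-pairs distance checks, explicit
flood fill) so the production code can be checked against an
independent route.
"""

from collections import deque

import numpy as np

CLASS_NODATA = 255


def brute_classify_grid(table, values):
    """Per-cell loop over classify_value."""
    from palmrisk.rules import RiskClass, classify_value

    arr = np.asarray(values)
    out = np.full(arr.shape, CLASS_NODATA, dtype=np.uint8)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            cls = classify_value(table, arr[i, j])
            out[i, j] = CLASS_NODATA if cls is RiskClass.NODATA else cls.rank
    return out


def brute_point_in_polygons(polygons, template):
    """Cell-center point-in-polygon by per-cell shapely queries."""
    from shapely.geometry import Point

    out = np.zeros((template.n_rows, template.n_cols), dtype=np.uint8)
    for i in range(template.n_rows):
        for j in range(template.n_cols):
            x = template.x_origin + (j + 0.5) * template.cell_size
            y = template.y_origin - (i + 0.5) * template.cell_size
            pt = Point(x, y)
            if any(p.contains(pt) or p.boundary.contains(pt) for p in polygons):
                out[i, j] = 1
    return out


def brute_distance_buffer(mask_cells, cell_size, distance_m):
    """All-pairs center-to-center Euclidean distance check."""
    mask = np.asarray(mask_cells)
    rows, cols = np.nonzero(mask == 1)
    out = np.zeros(mask.shape, dtype=np.uint8)
    if rows.size == 0:
        return out
    ii, jj = np.indices(mask.shape)
    d2 = (
        (ii[..., None] - rows[None, None, :]) ** 2
        + (jj[..., None] - cols[None, None, :]) ** 2
    ).min(axis=-1)
    dist = np.sqrt(d2.astype(float)) * cell_size
    return (dist <= distance_m * (1 + 1e-9)).astype(np.uint8)


def brute_flood_fill_labels(mask_cells, connectivity):
    """BFS flood fill; labels assigned in scan order starting at 1."""
    mask = np.asarray(mask_cells)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                 if (di, dj) != (0, 0)]
    next_label = 0
    for si in range(mask.shape[0]):
        for sj in range(mask.shape[1]):
            if mask[si, sj] != 1 or labels[si, sj]:
                continue
            next_label += 1
            queue = deque([(si, sj)])
            labels[si, sj] = next_label
            while queue:
                i, j = queue.popleft()
                for di, dj in steps:
                    ni, nj = i + di, j + dj
                    if (
                        0 <= ni < mask.shape[0]
                        and 0 <= nj < mask.shape[1]
                        and mask[ni, nj] == 1
                        and not labels[ni, nj]
                    ):
                        labels[ni, nj] = next_label
                        queue.append((ni, nj))
    return labels, next_label


def brute_liebig(stacks, nodata_policy="ignore"):
    """Per-cell python loop over the layer list."""
    shape = stacks[0].shape
    out = np.full(shape, CLASS_NODATA, dtype=np.uint8)
    for i in range(shape[0]):
        for j in range(shape[1]):
            vals = [int(s[i, j]) for s in stacks]
            present = [v for v in vals if v != CLASS_NODATA]
            if not present:
                continue
            if nodata_policy == "propagate" and len(present) < len(vals):
                continue
            out[i, j] = max(present)
    return out


def brute_class_counts(cells):
    """Histogram of class ranks by explicit iteration."""
    counts = {0: 0, 1: 0, 2: 0, 3: 0}
    for v in np.asarray(cells).ravel():
        v = int(v)
        if v in counts:
            counts[v] += 1
    return counts


def brute_joint_histogram(rim_cells, zone_cells):
    """(zone code, class rank) -> count by explicit double loop."""
    rim = np.asarray(rim_cells)
    zones = np.asarray(zone_cells)
    joint: dict[tuple[int, int], int] = {}
    for i in range(rim.shape[0]):
        for j in range(rim.shape[1]):
            r = int(rim[i, j])
            if r == CLASS_NODATA:
                continue
            key = (int(zones[i, j]), r)
            joint[key] = joint.get(key, 0) + 1
    return joint
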