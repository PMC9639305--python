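"""Independent brute-force oracle for the n-SD segmentation pipeline.

Deliberately written as one straight-line function with explicit Python
loops and its own BFS flood fill, sharing no code with the package.
"""

import math


def segment_slice_oracle(image, myo_mask, roi_mask, n, remove_spurious, min_island, connectivity):
    h = len(image)
    w = len(image[0])

    # remote ROI statistics: mean and sample SD (ddof=1)
    vals = []
    for y in range(h):
        for x in range(w):
            if roi_mask[y][x]:
                vals.append(float(image[y][x]))
    mu = sum(vals) / len(vals)
    if len(vals) > 1:
        sigma = math.sqrt(sum((v - mu) ** 2 for v in vals) / (len(vals) - 1))
    else:
        sigma = 0.0
    threshold = mu + n * sigma

    # per-pixel strict comparison inside the myocardium
    mask = [[False] * w for _ in range(h)]
    for y in range(h):
        for x in range(w):
            if myo_mask[y][x] and float(image[y][x]) > threshold:
                mask[y][x] = True

    if remove_spurious:
        if connectivity == 4:
            nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        else:
            nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
        seen = [[False] * w for _ in range(h)]
        for y0 in range(h):
            for x0 in range(w):
                if mask[y0][x0] and not seen[y0][x0]:
                    comp = []
                    stack = [(y0, x0)]
                    seen[y0][x0] = True
                    while stack:
                        y, x = stack.pop()
                        comp.append((y, x))
                        for dy, dx in nbrs:
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w and mask[yy][xx] and not seen[yy][xx]:
                                seen[yy][xx] = True
                                stack.append((yy, xx))
                    if len(comp) < min_island:
                        for y, x in comp:
                            mask[y][x] = False

    myo_count = 0
    inf_count = 0
    for y in range(h):
        for x in range(w):
            if myo_mask[y][x]:
                myo_count += 1
                if mask[y][x]:
                    inf_count += 1
    pct = 100.0 * inf_count / myo_count

    import numpy as np

    return np.array(mask, dtype=bool), pct, threshold
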