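"""Independent brute-force oracles used to check the library implementations.

Everything here is written naively (per-pixel loops, exhaustive enumeration,
pair counting) and shares no code with the package.
"""

import numpy as np


def point_in_polygon_evenodd(x, y, rings):
    """Even-odd crossing-number test over a list of rings (shell + holes)."""
    crossings = 0
    for ring in rings:
        pts = np.asarray(ring, dtype=float)
        n = len(pts)
        for i in range(n):
            x1, y1 = pts[i]
            x2, y2 = pts[(i + 1) % n]
            if (y1 > y) != (y2 > y):
                x_at = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                if x_at > x:
                    crossings += 1
    return crossings % 2 == 1


def brute_rasterize(rings, shape):
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            mask[r, c] = point_in_polygon_evenodd(c, r, rings)
    return mask


def brute_tile_positions(mask, tile, stride):
    """(row, col, all_inside) for every grid tile of one label mask."""
    h, w = mask.shape
    out = []
    for r in range(0, h - tile + 1, stride):
        for c in range(0, w - tile + 1, stride):
            out.append((r, c, bool(mask[r:r + tile, c:c + tile].all())))
    return out


def brute_anchor_axis(extent, window, step):
    anchors = []
    a = 0
    while a + window <= extent:
        anchors.append(a)
        a += step
    if anchors[-1] != extent - window:
        anchors.append(extent - window)
    return anchors


def brute_aggregate(slide_pixels, model, window, step):
    """Naive double-loop accumulate-and-divide confidence map."""
    h, w = slide_pixels.shape[:2]
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w), dtype=int)
    for r in brute_anchor_axis(h, window, step):
        for c in brute_anchor_axis(w, window, step):
            conf = float(np.asarray(
                model.predict(slide_pixels[r:r + window, c:c + window][None])
            )[0])
            acc[r:r + window, c:c + window] += conf
            cnt[r:r + window, c:c + window] += 1
    mean = np.full((h, w), -1.0)
    mean[cnt > 0] = acc[cnt > 0] / cnt[cnt > 0]
    return mean, cnt


def brute_f1(confidences, labels, threshold):
    pred = np.asarray(confidences) >= threshold
    truth = np.asarray(labels).astype(bool)
    tp = np.sum(pred & truth)
    fp = np.sum(pred & ~truth)
    fn = np.sum(~pred & truth)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


def brute_sweep(confidences, labels, grid_step=0.01):
    n = int(round(1 / grid_step))
    best_t, best_f1 = None, -1.0
    grid = [min(i * grid_step, 1.0) for i in range(n + 1)]
    f1s = []
    for t in grid:
        f1 = brute_f1(confidences, labels, t)
        f1s.append(f1)
        if f1 > best_f1:
            best_f1, best_t = f1, t
    return np.array(grid), np.array(f1s), best_t, best_f1


def make_simple_polygon(rng, extent, n_min=3, n_max=8):
    """Random simple polygon with no pixel center on its boundary.

    Vertices are sorted by angle around the centroid (star-shaped, hence
    simple when angles are distinct); draws are rejected until the polygon is
    valid and every pixel center is strictly inside or outside, so the
    even-odd oracle and boundary-inclusive rasterizers cannot disagree.
    """
    import shapely
    from shapely.geometry import Polygon

    while True:
        n = int(rng.integers(n_min, n_max + 1))
        pts = rng.uniform(1, extent - 2, (n, 2))
        order = np.argsort(np.arctan2(*(pts - pts.mean(0)).T[::-1]))
        poly = pts[order]
        shp = Polygon(poly)
        if not shp.is_valid or shp.area < 1:
            continue
        cols, rows = np.meshgrid(np.arange(extent), np.arange(extent))
        on_boundary = shapely.dwithin(
            shapely.points(np.c_[cols.ravel(), rows.ravel()]),
            shp.boundary, 1e-7)
        if not on_boundary.any():
            return poly


def pair_count_auroc(confidences, labels):
    """Mann-Whitney: fraction of concordant positive/negative pairs."""
    confidences = np.asarray(confidences, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = confidences[labels == 1]
    neg = confidences[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
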