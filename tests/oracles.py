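"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive (pure-Python loops, no vectorisation, no shared
code with the package) so they constitute a second route to the same
definitions.
"""

from __future__ import annotations

from collections import deque


def flood_fill_components(mask) -> list[tuple[int, int, int, int, int]]:
    """8-connected components of a boolean grid via BFS flood fill.

    Returns one (x, y, w, h, area) tuple per component, sorted by (x, y) of
    the tight bounding box.
    """
    rows = len(mask)
    cols = len(mask[0]) if rows else 0
    seen = [[False] * cols for _ in range(rows)]
    out = []
    for r0 in range(rows):
        for c0 in range(cols):
            if not mask[r0][c0] or seen[r0][c0]:
                continue
            queue = deque([(r0, c0)])
            seen[r0][c0] = True
            pixels = []
            while queue:
                r, c = queue.popleft()
                pixels.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < rows
                            and 0 <= cc < cols
                            and mask[rr][cc]
                            and not seen[rr][cc]
                        ):
                            seen[rr][cc] = True
                            queue.append((rr, cc))
            ys = [p[0] for p in pixels]
            xs = [p[1] for p in pixels]
            out.append(
                (min(xs), min(ys), max(xs) - min(xs) + 1, max(ys) - min(ys) + 1,
                 len(pixels))
            )
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def pairwise_auc(scores, labels) -> float:
    """AUC as the fraction of concordant (positive, negative) pairs, ties 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        raise ValueError("both classes required")
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def _sweep_points(scores, labels):
    """(fpr, fnr) at every achievable decision threshold, swept high to low."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        raise ValueError("both classes required")
    thresholds = sorted(set(scores), reverse=True)
    points = [(0.0, 1.0)]  # nothing predicted positive
    for t in thresholds:
        fp = sum(1 for s in neg if s >= t)
        fn = sum(1 for s in pos if s < t)
        points.append((fp / len(neg), fn / len(pos)))
    return points


def sweep_eer(scores, labels) -> float:
    """EER from an exhaustive threshold sweep.

    Walks the (fpr, fnr) polyline from the strictest threshold down and
    linearly interpolates inside the segment where fpr crosses fnr.
    """
    points = _sweep_points(scores, labels)
    for i, (fp, fn) in enumerate(points):
        if fp >= fn:
            if i == 0:
                return fp
            fp1, fn1 = points[i - 1]
            denom = (fp - fp1) - (fn - fn1)
            if denom == 0:
                return (fp1 + fn1) / 2.0
            frac = (fn1 - fp1) / denom
            return fp1 + frac * (fp - fp1)
    return points[-1][0]
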