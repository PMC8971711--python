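"""Shared test oracles: deliberately simple, independent re-implementations."""

import numpy as np


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    s = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / s if s else 1.0


def otsu_oracle(values, n_bins=256):
    """Exhaustive between-class-variance search over all interior bin edges.

    Exact ties (plateaus across empty bins) resolve to the lowest edge, with
    a relative tolerance so float accumulation noise cannot flip the choice.
    """
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    total = counts.sum()
    sigmas = np.full(n_bins - 1, -np.inf)
    for b in range(n_bins - 1):
        w0 = counts[: b + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: b + 1] * centers[: b + 1]).sum() / w0
        mu1 = (counts[b + 1 :] * centers[b + 1 :]).sum() / w1
        sigmas[b] = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
    top = sigmas.max()
    best = int(np.flatnonzero(sigmas >= top - 1e-9 * abs(top))[0])
    return edges[best + 1]


def flood_fill_filter(mask, min_size):
    """Independent BFS flood fill under 26-connectivity with size filtering."""
    mask = np.asarray(mask, bool)
    visited = np.zeros_like(mask)
    out = np.zeros_like(mask)
    shape = mask.shape
    offsets = [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for d in offsets:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[a] < shape[a] for a in range(3)) and mask[w] and not visited[w]:
                    visited[w] = True
                    stack.append(w)
        if len(comp) >= min_size:
            for v in comp:
                out[v] = True
    return out
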