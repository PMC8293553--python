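"""Independent brute-force oracles for the mask operations.

These are deliberately naive (stack-based flood fills over Python sets) and
share no code with the package, so they can arbitrate connected-component
counting and hole filling on small random masks.
"""

from __future__ import annotations

import numpy as np

NEIGHBORS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
NEIGHBORS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def flood_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected foreground components as sets of (row, col) pixels."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            comp = set()
            stack = [(r, c)]
            seen[r, c] = True
            while stack:
                y, x = stack.pop()
                comp.add((y, x))
                for dy, dx in NEIGHBORS_8:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            comps.append(comp)
    return comps


def fill_holes_by_border_flood(mask: np.ndarray) -> np.ndarray:
    """Everything not reachable from the border through 4-connected
    background becomes foreground."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    outside = np.zeros_like(mask)
    stack = [
        (r, c)
        for r in range(h)
        for c in range(w)
        if (r in (0, h - 1) or c in (0, w - 1)) and not mask[r, c]
    ]
    for r, c in stack:
        outside[r, c] = True
    while stack:
        y, x = stack.pop()
        for dy, dx in NEIGHBORS_4:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not mask[ny, nx] and not outside[ny, nx]:
                outside[ny, nx] = True
                stack.append((ny, nx))
    return ~outside
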