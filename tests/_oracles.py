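"""Independent reference implementations used only to check results.

Everything here is deliberately naive (loops, textbook formulas, quadrature)
and shares no code with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

NEIGHBORS = {
    6: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) == 1],
    18: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if 0 < abs(dx) + abs(dy) + abs(dz) <= 2],
    26: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if (dx, dy, dz) != (0, 0, 0)],
}


def flood_fill_components(binary: np.ndarray, connectivity: int) -> list[int]:
    """Component sizes of a 3D boolean array by breadth-first flood fill."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    sizes = []
    nx, ny, nz = binary.shape
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        q = deque([start])
        seen[start] = True
        size = 0
        while q:
            x, y, z = q.popleft()
            size += 1
            for dx, dy, dz in NEIGHBORS[connectivity]:
                p = (x + dx, y + dy, z + dz)
                if (0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz
                        and binary[p] and not seen[p]):
                    seen[p] = True
                    q.append(p)
        sizes.append(size)
    return sorted(sizes)


def pooled_two_sample_t(a: np.ndarray, b: np.ndarray) -> float:
    """Classical pooled-variance two-sample t (a minus b), textbook formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float((a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb)))


def student_t_two_tailed_p(t: float, df: int) -> float:
    """Two-tailed p by numerical quadrature of the Student-t density."""
    from scipy.integrate import quad

    c = math.gamma((df + 1) / 2.0) / (math.sqrt(df * math.pi) * math.gamma(df / 2.0))

    def pdf(x: float) -> float:
        return c * (1.0 + x * x / df) ** (-(df + 1) / 2.0)

    tail, _ = quad(pdf, abs(t), np.inf)
    return 2.0 * tail


def ols_residuals(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Residuals of y on [1, t] via explicit normal equations."""
    X = np.column_stack([np.ones_like(t, dtype=float), t.astype(float)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta
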