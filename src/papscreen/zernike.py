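"""Zernike moments on square image windows.

Zernike polynomials v_nl(r, theta) = R_n|l|(r) * exp(i l theta) are orthogonal
on the unit disk.  The complex moment of an m x m patch I is

    A_nl = (n + 1) / pi * sum_{r <= 1} conj(v_nl) * I(x, y)

with the sum over pixel centres inside the unit disk inscribed in the window.
Moment magnitudes |A_nl| are invariant under rotation of the patch content,
which makes their per-pixel average a robust texture statistic: nuclei have a
narrow stain-intensity distribution while debris is texturally erratic, so
debris windows spread energy across many (n, l) orders.

Moments with n - |l| odd are identically zero by the parity of R_nl and are
excluded from the index set.  Only l >= 0 is enumerated since
|A_n,-l| = |A_nl|.
"""

from __future__ import annotations

from math import factorial

import numpy as np

from ._errors import ConfigError


def zernike_indices(n_max: int) -> list[tuple[int, int]]:
    """All (n, l) with 0 <= n <= n_max, 0 <= l <= n and n - l even."""
    return [(n, l) for n in range(n_max + 1) for l in range(n + 1) if (n - l) % 2 == 0]


def radial_polynomial(n: int, l: int, r: np.ndarray) -> np.ndarray:
    """Radial part R_nl of the Zernike polynomial, for l >= 0, n - l even."""
    out = np.zeros_like(r, dtype=float)
    for s in range((n - l) // 2 + 1):
        coef = (
            (-1) ** s
            * factorial(n - s)
            / (factorial(s) * factorial((n + l) // 2 - s) * factorial((n - l) // 2 - s))
        )
        out += coef * r ** (n - 2 * s)
    return out


class ZernikeBasis:
    """Precomputed conjugate Zernike basis for an m x m window.

    Pixel centres are mapped to the unit disk inscribed in the window
    (centre ((m-1)/2, (m-1)/2), radius (m-1)/2); pixels with r > 1 carry
    zero weight.  ``moments`` multiplies patches by the basis, yielding
    one complex A_nl per (n, l) pair.
    """

    def __init__(self, window: int = 25, n_max: int = 9):
        if window < 3:
            raise ConfigError("Zernike window must be at least 3 pixels")
        if n_max < 0:
            raise ConfigError("Zernike order must be non-negative")
        self.window = int(window)
        self.n_max = int(n_max)
        self.indices = zernike_indices(n_max)

        c = (window - 1) / 2.0
        yy, xx = np.mgrid[0:window, 0:window]
        x = (xx - c) / c
        y = (yy - c) / c
        r = np.hypot(x, y)
        theta = np.arctan2(y, x)
        inside = r <= 1.0

        basis = np.zeros((len(self.indices), window * window), dtype=complex)
        for k, (n, l) in enumerate(self.indices):
            v = radial_polynomial(n, l, r) * np.exp(1j * l * theta)
            v[~inside] = 0.0
            basis[k] = ((n + 1) / np.pi) * np.conj(v).ravel()
        self._basis = basis

    def moments(self, patch: np.ndarray) -> np.ndarray:
        """Complex A_nl vector for one m x m patch."""
        patch = np.asarray(patch, dtype=float)
        if patch.shape != (self.window, self.window):
            raise ConfigError(
                f"patch shape {patch.shape} does not match window {self.window}"
            )
        return self._basis @ patch.ravel()

    def moments_many(self, patches: np.ndarray) -> np.ndarray:
        """A_nl for a stack of flattened patches, shape (P, m*m) -> (P, K)."""
        return patches @ self._basis.T

    def magnitudes(self, patch: np.ndarray) -> np.ndarray:
        return np.abs(self.moments(patch))
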