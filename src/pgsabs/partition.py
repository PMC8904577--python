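"""Equal-mass quantile partitions of a score distribution."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pgsabs.errors import DomainError


@dataclass(frozen=True)
class QuantilePartition:
    """Ordered interval boundaries splitting the real line into n equal-mass cells.

    ``boundaries`` has length ``n_quantiles + 1`` with boundaries[0] = -inf
    and boundaries[-1] = +inf; interior boundaries are the distribution's
    i/n quantiles.  Cells are half-open on the left, ``(b[i-1], b[i]]``, so
    a score exactly on a boundary belongs to the lower cell.
    """

    n_quantiles: int
    boundaries: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_quantiles < 2:
            raise DomainError(f"n_quantiles must be >= 2, got {self.n_quantiles}")
        b = np.asarray(self.boundaries, dtype=float)
        if b.shape != (self.n_quantiles + 1,):
            raise DomainError(
                f"expected {self.n_quantiles + 1} boundaries, got {b.shape}"
            )
        if not (np.isneginf(b[0]) and np.isposinf(b[-1])):
            raise DomainError("outermost boundaries must be -inf and +inf")
        if not np.all(np.diff(b) > 0):
            raise DomainError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)

    def cell_of(self, z: float) -> int:
        """Index of the cell containing ``z`` (0-based; boundary goes to the lower cell)."""
        if not np.isfinite(z):
            raise DomainError(f"score must be finite, got {z}")
        # side='left' on searchsorted gives (b[i-1], b[i]] semantics
        idx = int(np.searchsorted(self.boundaries, z, side="left")) - 1
        return min(max(idx, 0), self.n_quantiles - 1)

    def cell_bounds(self, i: int) -> tuple[float, float]:
        """Boundaries (lower, upper] of cell ``i``."""
        if not 0 <= i < self.n_quantiles:
            raise DomainError(f"cell index {i} out of range [0, {self.n_quantiles})")
        return float(self.boundaries[i]), float(self.boundaries[i + 1])
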