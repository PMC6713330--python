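"""Square-lattice description of the 2-D tissue domain."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Grid:
    """Uniform 2-D grid: ``n_x`` x ``n_y`` points with spacing ``h`` (mm).

    Fields are stored as arrays of shape (n_y, n_x); x is the second
    (column) axis.  The physical domain size is L_x x L_y with
    L_i = n_i * h, area A = L_x * L_y (mm^2).
    """

    n_x: int
    n_y: int
    h: float

    def __post_init__(self):
        if self.n_x < 3 or self.n_y < 3:
            raise ValueError("grid needs at least 3 points per direction")
        if self.h <= 0:
            raise ValueError("grid spacing h must be > 0")

    @classmethod
    def square(cls, L: float, h: float) -> "Grid":
        """Square domain of side L mm at spacing h."""
        n = int(round(L / h))
        return cls(n_x=n, n_y=n, h=h)

    @property
    def L_x(self) -> float:
        return self.n_x * self.h

    @property
    def L_y(self) -> float:
        return self.n_y * self.h

    @property
    def area(self) -> float:
        """Domain area A = L_x * L_y in mm^2."""
        return self.L_x * self.L_y

    @property
    def shape(self):
        return (self.n_y, self.n_x)
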