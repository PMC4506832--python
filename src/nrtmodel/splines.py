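"""Truncated-power cubic spline basis in frequency.

The NRT-threshold-vs-frequency relation is modelled as a piecewise cubic
polynomial with knots at 5000 and 10000 Hz, expressed on the truncated-power
basis ``[f, f^2, f^3, (f - k1)^3_+, (f - k2)^3_+]`` (the intercept is carried
by the design matrix, not the basis).  A function in the span of this basis
is C^2: continuous with continuous first and second derivatives across each
knot, with a jump only in the third derivative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_KNOTS_HZ", "SplineBasisSpec", "build_spline_basis", "spline_column_names"]

DEFAULT_KNOTS_HZ = (5000.0, 10000.0)


@dataclass(frozen=True)
class SplineBasisSpec:
    """Knot locations (Hz) of the cubic truncated-power basis."""

    knots: tuple[float, ...] = DEFAULT_KNOTS_HZ
    degree: int = 3

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if np.any(k <= 0):
            raise ValueError("knots must be positive frequencies")
        if np.any(np.diff(k) <= 0):
            raise ValueError("knots must be strictly increasing")
        if self.degree != 3:
            raise ValueError("only the cubic basis is supported")

    @property
    def n_columns(self) -> int:
        return self.degree + len(self.knots)


def spline_column_names(prefix: str = "cnf", spec: SplineBasisSpec | None = None) -> list[str]:
    spec = spec or SplineBasisSpec()
    names = [f"{prefix}_f", f"{prefix}_f2", f"{prefix}_f3"]
    names += [f"{prefix}_tp{i + 1}" for i in range(len(spec.knots))]
    return names


def build_spline_basis(
    f,
    spec: SplineBasisSpec | None = None,
    prefix: str = "cnf",
) -> pd.DataFrame:
    """Evaluate the cubic truncated-power basis at frequencies ``f`` (Hz).

    Returns a DataFrame with columns ``[f, f^2, f^3]`` plus one truncated
    cubic ``(f - k)^3_+`` per knot.  Frequencies must be positive.
    """
    spec = spec or SplineBasisSpec()
    f = np.atleast_1d(np.asarray(f, dtype=float))
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    cols = {f"{prefix}_f": f, f"{prefix}_f2": f**2, f"{prefix}_f3": f**3}
    for i, k in enumerate(spec.knots):
        cols[f"{prefix}_tp{i + 1}"] = np.clip(f - k, 0.0, None) ** 3
    return pd.DataFrame(cols)
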