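"""Natural cubic spline bases for the behavioural rate surfaces.

A natural cubic spline with K knots is cubic between knots, C2 everywhere,
and linear beyond the boundary knots.  The basis here is the textbook
truncated-power construction: with knots xi_1 < ... < xi_K,

    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k)
    N_1(x) = x,   N_{k+1}(x) = d_k(x) - d_{K-1}(x)   (k = 1..K-2)

giving df = K - 1 basis functions, the intercept being handled separately by
the model's coefficient blocks.  ``df = 1`` degenerates to the centred linear
term.  Columns can carry an affine standardisation (centre/scale), used to
make the spline coefficient priors data-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SplineSpec", "natural_cubic_basis"]


@dataclass(frozen=True)
class SplineSpec:
    """Domain, dimension and knots of one natural cubic spline term."""

    domain: tuple[float, float]
    df: int
    knots: tuple[float, ...] = ()          # interior knots
    boundary_knots: tuple[float, float] | None = None
    centres: tuple[float, ...] | None = None
    scales: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not hi > lo:
            raise ValueError("empty domain")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        bk = self.boundary_knots if self.boundary_knots is not None else (lo, hi)
        object.__setattr__(self, "boundary_knots", (float(bk[0]), float(bk[1])))
        kn = tuple(float(k) for k in self.knots)
        if list(kn) != sorted(set(kn)):
            raise ValueError("interior knots must be strictly increasing")
        if kn and not (bk[0] < kn[0] and kn[-1] < bk[1]):
            raise ValueError("interior knots must lie strictly inside boundary knots")
        if self.df >= 2 and len(kn) != self.df - 1:
            raise ValueError(
                f"df={self.df} requires {self.df - 1} interior knots, got {len(kn)}")
        if self.df == 1 and kn:
            raise ValueError("df=1 takes no interior knots")
        object.__setattr__(self, "knots", kn)

    @classmethod
    def equally_spaced(cls, lo: float, hi: float, df: int) -> "SplineSpec":
        """Boundary knots at the domain ends, interior knots equally spaced."""
        if df >= 2:
            interior = tuple(np.linspace(lo, hi, df + 1)[1:-1])
        else:
            interior = ()
        return cls(domain=(float(lo), float(hi)), df=df, knots=interior)

    @property
    def all_knots(self) -> np.ndarray:
        return np.array([self.boundary_knots[0], *self.knots,
                         self.boundary_knots[1]])

    def standardised_over(self, x_obs: np.ndarray) -> "SplineSpec":
        """Spec whose basis columns have mean 0, SD 1 over ``x_obs``.

        This is the data dependence of the spline coefficient priors: a unit
        coefficient then moves the linear predictor by about one SD of the
        basis function over the observed covariate values.
        """
        raw = _raw_basis(np.asarray(x_obs, dtype=float), self)
        centres = raw.mean(axis=0)
        scales = raw.std(axis=0)
        # a (near-)constant column over the observed values (e.g. a single
        # survey year) keeps unit scale instead of exploding
        scales = np.where(scales > 1e-6, scales, 1.0)
        return replace(self, centres=tuple(centres), scales=tuple(scales))


def _raw_basis(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    lo, hi = spec.domain
    mid = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    cols = [(x - mid) / half]
    if spec.df >= 2:
        xi = spec.all_knots
        K = xi.size
        span = hi - lo

        def d(k):
            num = (np.maximum(x - xi[k], 0.0) ** 3
                   - np.maximum(x - xi[K - 1], 0.0) ** 3)
            return num / (xi[K - 1] - xi[k])

        d_last = d(K - 2)
        for k in range(K - 2):
            cols.append((d(k) - d_last) / span ** 2)  # rescale for conditioning
    return np.column_stack(cols)


def natural_cubic_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the basis at ``x``; returns shape (len(x), df).

    Natural boundary behaviour: every column is exactly linear beyond the
    boundary knots.  Standardisation from the spec (if any) is applied.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    B = _raw_basis(x, spec)
    if spec.centres is not None:
        B = (B - np.asarray(spec.centres)) / np.asarray(spec.scales)
    return B
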