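"""Greenwood cochlear frequency-position map and filterbank band-edge design.

The Greenwood function maps normalized cochlear position ``x`` (0 = apex,
1 = base) to characteristic frequency

    f(x) = A * (10**(a*x) - k)

with the standard human constants A = 165.4 Hz, a = 2.1, k = 0.88.
Band edges spaced uniformly in ``x`` give filter bands of approximately
equal cochlear extent, the conventional spacing for vocoder-style
channel processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GreenwoodParams",
    "HUMAN",
    "greenwood_frequency",
    "greenwood_position",
    "FilterBankSpec",
    "design_band_edges",
]


@dataclass(frozen=True)
class GreenwoodParams:
    """Constants of the Greenwood frequency-position function."""

    A: float = 165.4  # Hz scale
    a: float = 2.1    # exponent coefficient per unit position
    k: float = 0.88   # apical offset

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.a > 0 and 0 <= self.k < 1):
            raise ValueError("require A > 0, a > 0, 0 <= k < 1")


#: Standard human cochlear map.
HUMAN = GreenwoodParams()


def greenwood_frequency(x, params: GreenwoodParams = HUMAN):
    """Characteristic frequency (Hz) at normalized cochlear position ``x``.

    ``x`` must lie in [0, 1]; scalar or array. Strictly increasing in ``x``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("cochlear position must lie in [0, 1]")
    f = params.A * (10.0 ** (params.a * x) - params.k)
    return float(f) if f.ndim == 0 else f


def greenwood_position(f, params: GreenwoodParams = HUMAN):
    """Inverse map: normalized cochlear position of frequency ``f`` (Hz).

    Requires ``f / A + k > 0``. Exact inverse of :func:`greenwood_frequency`
    (round-trips to machine precision).
    """
    f = np.asarray(f, dtype=float)
    arg = f / params.A + params.k
    if np.any(arg <= 0):
        raise ValueError("frequency below the physical range of the map")
    x = np.log10(arg) / params.a
    return float(x) if x.ndim == 0 else x


@dataclass(frozen=True)
class FilterBankSpec:
    """Band edges and filter parameters for the bandpass decomposition.

    ``edges`` holds ``n_bands + 1`` strictly increasing corner frequencies,
    equally spaced in Greenwood position between ``f_low`` and ``f_high``.
    """

    f_low: float = 80.0
    f_high: float = 7562.0
    n_bands: int = 30
    filter_order: int = 3
    passband_ripple_db: float = 1.0
    stopband_atten_db: float = 50.0
    edges: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.edges is None:
            object.__setattr__(
                self,
                "edges",
                _greenwood_edges(self.f_low, self.f_high, self.n_bands),
            )
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if edges.shape != (self.n_bands + 1,):
            raise ValueError("need n_bands + 1 edges")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")

    def band_edges(self, i: int) -> tuple[float, float]:
        """(low, high) corner frequencies of band ``i`` in Hz."""
        return float(self.edges[i]), float(self.edges[i + 1])


def _greenwood_edges(
    f_low: float, f_high: float, n_bands: int, params: GreenwoodParams = HUMAN
) -> np.ndarray:
    if not (0 < f_low < f_high):
        raise ValueError("require 0 < f_low < f_high")
    if n_bands < 1:
        raise ValueError("need at least one band")
    x = np.linspace(
        greenwood_position(f_low, params), greenwood_position(f_high, params),
        n_bands + 1,
    )
    edges = greenwood_frequency(x, params)
    # pin the end points exactly despite round-trip rounding
    edges[0], edges[-1] = f_low, f_high
    return edges


def design_band_edges(
    f_low: float = 80.0,
    f_high: float = 7562.0,
    n_bands: int = 30,
    params: GreenwoodParams = HUMAN,
    **filter_kwargs,
) -> FilterBankSpec:
    """Build a :class:`FilterBankSpec` with Greenwood-spaced corner frequencies."""
    edges = _greenwood_edges(f_low, f_high, n_bands, params)
    return FilterBankSpec(
        f_low=f_low, f_high=f_high, n_bands=n_bands, edges=edges, **filter_kwargs
    )
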