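"""Bivariate and value-suppressing uncertainty palettes (VSUP).

A VSUP quantizes (value, uncertainty) pairs onto a wedge: uncertainty picks
a layer, and the number of distinguishable value bins shrinks geometrically
with the layer — at the most uncertain layer every value collapses into a
single bin.  The idea is that uncertain values should not be visually
distinguishable, so attention is drawn to the hexes (or points) whose
predictions the model is actually confident about.  A plain bivariate
palette (independent value x uncertainty grid) is provided as the
non-suppressing alternative.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib.colors import to_hex

from .ro_dataset import RoDatasetError

__all__ = [
    "VSUPPalette",
    "BivariatePalette",
    "vsup_bin",
    "bivariate_bin",
    "bin_to_color",
    "palette_colors",
    "quantize_layer",
]


@dataclass(frozen=True)
class VSUPPalette:
    """Quantization tree mapping (value, uncertainty) to a discrete bin.

    Layer 0 (most certain) has ``branching ** (layers - 1)`` value bins;
    each subsequent layer divides the bin count by ``branching`` until the
    most uncertain layer has exactly one.  Total bins =
    (b^L - 1)/(b - 1).  Uncertainty layering is equal-width by default;
    ``uncertainty_edges`` (e.g. quantiles of observed uncertainties)
    overrides it.
    """

    layers: int = 4
    branching: int = 3
    value_domain: tuple[float, float] = (0.0, 1.0)
    uncertainty_domain: tuple[float, float] = (0.0, 1.0)
    colormap_name: str = "viridis"
    uncertainty_edges: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.layers < 2 or self.branching < 2:
            raise RoDatasetError("VSUP needs layers >= 2 and branching >= 2")
        if self.value_domain[1] <= self.value_domain[0]:
            raise RoDatasetError("value domain must be non-degenerate")
        if self.uncertainty_domain[1] <= self.uncertainty_domain[0]:
            raise RoDatasetError("uncertainty domain must be non-degenerate")
        if self.uncertainty_edges is not None and len(self.uncertainty_edges) != (
            self.layers - 1
        ):
            raise RoDatasetError("uncertainty_edges must have layers - 1 entries")

    def bins_at_layer(self, layer: int) -> int:
        return self.branching ** (self.layers - 1 - layer)

    @property
    def total_bins(self) -> int:
        return (self.branching**self.layers - 1) // (self.branching - 1)

    @classmethod
    def from_data(
        cls,
        values,
        uncertainties,
        layers: int = 4,
        branching: int = 3,
        layering: str = "equal_width",
        **kw,
    ) -> "VSUPPalette":
        """Palette with domains from observed data; quantile layering optional."""
        values = np.asarray(values, float)
        unc = np.asarray(uncertainties, float)
        vd = (float(np.nanmin(values)), float(np.nanmax(values)))
        ud = (float(np.nanmin(unc)), float(np.nanmax(unc)))
        if vd[1] <= vd[0]:
            vd = (vd[0], vd[0] + 1.0)
        if ud[1] <= ud[0]:
            ud = (ud[0], ud[0] + 1.0)
        edges = None
        if layering == "quantile":
            qs = np.linspace(0, 1, layers + 1)[1:-1]
            edges = tuple(float(e) for e in np.nanquantile(unc, qs))
        elif layering != "equal_width":
            raise RoDatasetError(f"unknown layering {layering!r}")
        return cls(
            layers=layers,
            branching=branching,
            value_domain=vd,
            uncertainty_domain=ud,
            uncertainty_edges=edges,
            **kw,
        )


@dataclass(frozen=True)
class BivariatePalette:
    """Independent value x uncertainty grid (no suppression)."""

    n_value_bins: int = 4
    n_uncertainty_bins: int = 4
    value_domain: tuple[float, float] = (0.0, 1.0)
    uncertainty_domain: tuple[float, float] = (0.0, 1.0)
    colormap_name: str = "viridis"

    def __post_init__(self):
        if self.n_value_bins < 1 or self.n_uncertainty_bins < 1:
            raise RoDatasetError("bin counts must be >= 1")
        if self.value_domain[1] <= self.value_domain[0]:
            raise RoDatasetError("value domain must be non-degenerate")
        if self.uncertainty_domain[1] <= self.uncertainty_domain[0]:
            raise RoDatasetError("uncertainty domain must be non-degenerate")

    @property
    def total_bins(self) -> int:
        return self.n_value_bins * self.n_uncertainty_bins


def _uniform_bin(x: float, lo: float, hi: float, n: int) -> int:
    return int(np.clip(np.floor(n * (x - lo) / (hi - lo)), 0, n - 1))


def vsup_bin(value: float, uncertainty: float, palette: VSUPPalette) -> tuple[int, int]:
    """Map (value, uncertainty) to a (layer, bin) of the VSUP wedge.

    The layer grows with uncertainty; the value bin index is an equal-width
    quantization with ``branching ** (layers - 1 - layer)`` bins.  Inputs
    outside the domains clamp to the boundary bins.
    """
    if not (np.isfinite(value) and np.isfinite(uncertainty)):
        raise RoDatasetError("vsup_bin requires finite inputs")
    if palette.uncertainty_edges is not None:
        layer = int(np.searchsorted(palette.uncertainty_edges, uncertainty, side="left"))
    else:
        u_lo, u_hi = palette.uncertainty_domain
        layer = _uniform_bin(uncertainty, u_lo, u_hi, palette.layers)
    n_bins = palette.bins_at_layer(layer)
    v_lo, v_hi = palette.value_domain
    j = _uniform_bin(value, v_lo, v_hi, n_bins)
    return layer, j


def bivariate_bin(
    value: float, uncertainty: float, palette: BivariatePalette
) -> tuple[int, int]:
    """Independent equal-width binning of value and uncertainty (clamped)."""
    if not (np.isfinite(value) and np.isfinite(uncertainty)):
        raise RoDatasetError("bivariate_bin requires finite inputs")
    i = _uniform_bin(uncertainty, *palette.uncertainty_domain, palette.n_uncertainty_bins)
    j = _uniform_bin(value, *palette.value_domain, palette.n_value_bins)
    return i, j


# ---------------------------------------------------------------------------
# Colors
# ---------------------------------------------------------------------------

_NEUTRAL = (0.82, 0.82, 0.82)


def _desaturate(rgb, t: float):
    """Blend toward neutral gray and reduce HLS saturation by fraction t."""
    h, l, s = colorsys.rgb_to_hls(*rgb)
    r, g, b = colorsys.hls_to_rgb(h, l, s * (1.0 - t))
    return tuple(
        (1.0 - t) * c + t * n for c, n in zip((r, g, b), _NEUTRAL)
    )


def bin_to_color(bin_: tuple[int, int], palette) -> tuple[float, float, float]:
    """Deterministic RGB for a palette bin.

    Hue comes from the value-bin midpoint through the named colormap; the
    color is desaturated toward neutral as uncertainty grows (for a VSUP,
    the top layer is the most washed out).  Distinct bins of one palette map
    to distinct colors.
    """
    try:
        cmap = colormaps[palette.colormap_name]
    except KeyError as exc:
        raise RoDatasetError(f"unknown colormap {palette.colormap_name!r}") from exc
    if isinstance(palette, VSUPPalette):
        layer, j = bin_
        if not (0 <= layer < palette.layers and 0 <= j < palette.bins_at_layer(layer)):
            raise RoDatasetError(f"invalid VSUP bin {bin_!r}")
        mid = (j + 0.5) / palette.bins_at_layer(layer)
        t = 0.85 * layer / (palette.layers - 1)
    elif isinstance(palette, BivariatePalette):
        i, j = bin_
        if not (0 <= i < palette.n_uncertainty_bins and 0 <= j < palette.n_value_bins):
            raise RoDatasetError(f"invalid bivariate bin {bin_!r}")
        mid = (j + 0.5) / palette.n_value_bins
        t = (
            0.85 * i / (palette.n_uncertainty_bins - 1)
            if palette.n_uncertainty_bins > 1
            else 0.0
        )
    else:
        raise RoDatasetError(f"unsupported palette type {type(palette).__name__}")
    rgb = cmap(float(mid))[:3]
    return _desaturate(rgb, t)


def palette_colors(palette: VSUPPalette) -> dict[tuple[int, int], tuple]:
    """All (layer, bin) -> RGB entries of a VSUP wedge."""
    out = {}
    for layer in range(palette.layers):
        for j in range(palette.bins_at_layer(layer)):
            out[(layer, j)] = bin_to_color((layer, j), palette)
    return out


def quantize_layer(values, uncertainties, palette) -> pd.DataFrame:
    """Quantize aligned value/uncertainty arrays; one bin + color per entry.

    Returns a DataFrame with columns ``layer``, ``bin``, ``hexcolor`` —
    the export format used to attach palette bins to a hex-aggregated layer.
    """
    values = np.asarray(values, float)
    uncertainties = np.asarray(uncertainties, float)
    if values.shape != uncertainties.shape:
        raise RoDatasetError("values and uncertainties must align")
    binfn = vsup_bin if isinstance(palette, VSUPPalette) else bivariate_bin
    layers, bins, colors = [], [], []
    for v, u in zip(values, uncertainties):
        layer, j = binfn(float(v), float(u), palette)
        layers.append(layer)
        bins.append(j)
        colors.append(to_hex(bin_to_color((layer, j), palette)))
    return pd.DataFrame({"layer": layers, "bin": bins, "hexcolor": colors})
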