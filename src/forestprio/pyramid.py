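"""Block aggregation of the baseline stack to coarser analysis resolutions.

Every coarse stack derives directly from the 16 m baseline (never chained
through intermediate resolutions), with the rule bound to the variable:
Hmean by block mean, Hmax by block max, Vol and DDWVol by block sum.  The
default resolution set {16, 32, 48, 64, 80, 96} m tiles exactly on extents
divisible by 960 m (their least common multiple).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .features import FeatureLayer, FeatureStack

DEFAULT_RESOLUTIONS = (16, 32, 48, 64, 80, 96)


def cell_area_ratio(res_coarse: float, res_fine: float) -> float:
    """How many times larger a coarse cell's area is: (coarse/fine)**2."""
    if res_coarse <= 0 or res_fine <= 0:
        raise ValueError("resolutions must be > 0")
    return (res_coarse / res_fine) ** 2


def _block_view(values: np.ndarray, k: int) -> np.ndarray:
    nrows, ncols = values.shape
    return values.reshape(nrows // k, k, ncols // k, k).swapaxes(1, 2)


def aggregate_layer(
    layer: FeatureLayer,
    target_resolution: float,
    rule: str | None = None,
    mean_mode: str = "block",
) -> FeatureLayer:
    """Aggregate one layer to a coarser grid by block mean/max/sum.

    ``rule`` defaults to the one bound to the layer's variable.  ``mean_mode``
    controls how empty (zero) fine cells enter a block mean: ``"block"``
    (default) divides by the full block size, ``"occupied"`` by the count of
    nonzero fine cells.
    """
    ratio = target_resolution / layer.resolution
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"target resolution {target_resolution} is not an integer multiple "
            f"of {layer.resolution}"
        )
    nrows, ncols = layer.values.shape
    if nrows % k or ncols % k:
        raise ValueError(
            f"grid {nrows}x{ncols} does not tile into {k}x{k} blocks "
            f"for resolution {target_resolution}"
        )
    rule = rule or layer.rule
    blocks = _block_view(layer.values, k)
    if rule == "sum":
        coarse = blocks.sum(axis=(2, 3))
    elif rule == "max":
        coarse = blocks.max(axis=(2, 3))
    elif rule == "mean":
        if mean_mode == "block":
            coarse = blocks.mean(axis=(2, 3))
        elif mean_mode == "occupied":
            cnt = (blocks > 0).sum(axis=(2, 3))
            coarse = np.divide(
                blocks.sum(axis=(2, 3)), cnt, out=np.zeros((nrows // k, ncols // k)), where=cnt > 0
            )
        else:
            raise ValueError(f"unknown mean_mode {mean_mode!r}")
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return replace(layer, resolution=float(target_resolution), values=coarse)


def build_pyramid(
    stack16: FeatureStack,
    resolutions: tuple[float, ...] = DEFAULT_RESOLUTIONS,
    mean_mode: str = "block",
) -> dict[float, FeatureStack]:
    """Aggregate the baseline stack to every requested resolution.

    Returns a mapping resolution -> stack; the baseline itself is included
    unchanged.  With the default six resolutions and 52 baseline layers the
    pyramid holds 312 layers in total.
    """
    out: dict[float, FeatureStack] = {}
    for res in resolutions:
        if res == stack16.resolution:
            out[float(res)] = stack16
            continue
        layers = tuple(
            aggregate_layer(lyr, res, mean_mode=mean_mode) for lyr in stack16
        )
        out[float(res)] = FeatureStack(resolution=float(res), layers=layers)
    return out
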