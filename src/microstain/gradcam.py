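"""Gradient-weighted class activation maps for the tile classifier.

For a chosen convolutional layer, the class-score (logit) gradient is
averaged over space to give one weight per feature map; the ReLU of the
weighted feature-map sum, normalised by its maximum, is the heatmap. The
coarse map is bilinearly upsampled to tile resolution and can be blended
over the tile with a blue-to-red colormap (red = most class-relevant).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from PIL import Image
from skimage.transform import resize

from . import nn
from .tile_classifier import TilePredictionSeries, last_conv_layer, predict_tiles, tiles_to_array
from .tiling import TileSet

__all__ = ["Heatmap", "grad_cam", "overlay", "top_tiles", "save_heatmap_pair",
           "contact_sheet"]

BLUE_RED = LinearSegmentedColormap.from_list(
    "blue_red", [(0.0, 0.0, 0.8), (0.0, 0.8, 0.8), (0.9, 0.9, 0.2),
                 (0.9, 0.0, 0.0)])


@dataclass
class Heatmap:
    values: np.ndarray       # coarse H'xW' map in [0, 1]
    upsampled: np.ndarray    # tile-resolution map in [0, 1]
    layer: str


def grad_cam(model: nn.Sequential, tile: np.ndarray,
             target_layer: str | None = None) -> Heatmap:
    """Class-activation map of one tile from ``target_layer`` (default: the
    model's final convolutional layer).

    Channel weights are the spatial means of the logit gradient on the layer
    output; the map is the ReLU of the weighted sum, normalised by its max
    (an all-zero map stays all-zero).
    """
    target_layer = target_layer or last_conv_layer(model)
    layer = model[target_layer]
    if not isinstance(layer, nn.Conv2D):
        raise ValueError(f"target layer {target_layer!r} is not convolutional")
    dtype = next((l.params["W"].dtype for l in model.layers if l.has_params),
                 np.float32)
    x = np.asarray(tile, dtype=dtype)[None, ...]
    model.forward(x, keep_activations=True)
    fmap = model.activation(target_layer)[0]          # H' x W' x C
    model.backward(np.ones((1, 1)), capture=target_layer)
    grad = model.activation_gradient(target_layer)[0]
    weights = grad.mean(axis=(0, 1))                   # one weight per channel
    cam = np.maximum((fmap * weights).sum(axis=-1), 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    up = resize(cam, tile.shape[:2], order=1, preserve_range=True,
                anti_aliasing=False)
    up = np.clip(up, 0.0, 1.0)
    return Heatmap(values=cam.astype(np.float64), upsampled=up.astype(np.float64),
                   layer=target_layer)


def overlay(tile: np.ndarray, heatmap: Heatmap, alpha: float = 0.4) -> np.ndarray:
    """Blend the blue-to-red colormapped heatmap over the tile."""
    colored = BLUE_RED(heatmap.upsampled)[..., :3]
    return np.clip((1.0 - alpha) * tile + alpha * colored, 0.0, 1.0)


def top_tiles(model, tileset: TileSet, k: int,
              target_layer: str | None = None,
              ) -> list[tuple[int, float, Heatmap]]:
    """The k tiles most associated with the positive class, with heatmaps.

    Returns ``(tile_index, probability, heatmap)`` triples sorted by
    descending probability; ties break toward the lower tile index.
    """
    if len(tileset) == 0:
        raise ValueError("tileset is empty")
    if k > len(tileset):
        raise ValueError("k exceeds the number of tiles")
    series: TilePredictionSeries = predict_tiles(model, tileset)
    probs = series.probabilities
    order = sorted(range(len(probs)), key=lambda i: (-probs[i], i))[:k]
    backbone = getattr(model, "backbone", None)
    x = tiles_to_array(tileset, backbone.input_size if backbone else None)
    out = []
    for i in order:
        hm = grad_cam(model, x[i], target_layer)
        out.append((tileset.tiles[i].index, float(probs[i]), hm))
    return out


def _to_png(arr: np.ndarray, path: Path) -> None:
    Image.fromarray((np.clip(arr, 0, 1) * 255.0 + 0.5).astype(np.uint8)).save(path)


def save_heatmap_pair(tile: np.ndarray, heatmap: Heatmap, stem: Path,
                      alpha: float = 0.4) -> tuple[Path, Path]:
    """Write the raw map and the overlay as ``<stem>_map.png`` /
    ``<stem>_overlay.png``."""
    stem = Path(stem)
    raw = stem.with_name(stem.name + "_map.png")
    ovl = stem.with_name(stem.name + "_overlay.png")
    _to_png(BLUE_RED(heatmap.upsampled)[..., :3], raw)
    _to_png(overlay(tile, heatmap, alpha), ovl)
    return raw, ovl


def contact_sheet(tiles: list[np.ndarray], heatmaps: list[Heatmap],
                  path: Path, alpha: float = 0.4) -> Path:
    """Two-row panel (tiles above, overlays below) for quick review."""
    if len(tiles) != len(heatmaps) or not tiles:
        raise ValueError("need matching, non-empty tiles and heatmaps")
    top = np.concatenate(tiles, axis=1)
    bottom = np.concatenate([overlay(t, h, alpha)
                             for t, h in zip(tiles, heatmaps)], axis=1)
    _to_png(np.concatenate([top, bottom], axis=0), Path(path))
    return Path(path)
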