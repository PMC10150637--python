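"""Multi-layer feature-map fusion.

Deep networks describe an image at several depths: late layers are abstract
but coarse, earlier layers higher-resolution but less semantic.  Fusing
activation maps from different depths enriches the descriptor: maps are
spatially aligned by bilinear resampling to the smallest spatial size among
the inputs, then concatenated channel-wise.  Fusion is applied at two
successive levels (fuse two layers, then re-fuse the result with a third),
and the final stack is reduced to a flat feature vector by global average
pooling before classifier training.

The bilinear resampler uses the half-pixel-center convention
(align-corners-false): output sample i maps to source coordinate
``(i + 0.5) * scale - 0.5``.  Resampling to the source size is therefore an
exact identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FeatureMapStack",
    "FusedFeatureVector",
    "bilinear_resample",
    "fuse_maps",
    "two_level_fuse",
    "pool_to_vector",
]


@dataclass(frozen=True)
class FeatureMapStack:
    """Height x width x channels activation block from one network layer.

    ``channel_spans`` tracks which source layer contributed which channel
    range; a plain single-layer stack has one span covering all channels,
    and fusion concatenates spans alongside the channels.
    """

    values: np.ndarray
    source_tag: str = ""
    channel_spans: tuple[tuple[str, int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 2:
            values = values[:, :, None]
        if values.ndim != 3:
            raise ValueError(f"feature map must be HxWxC, got shape {values.shape}")
        if min(values.shape) < 1:
            raise ValueError(f"degenerate feature map shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature map contains non-finite values")
        object.__setattr__(self, "values", values)
        spans = tuple((str(t), int(a), int(b)) for t, a, b in self.channel_spans) or (
            (self.source_tag or "?", 0, values.shape[2]),
        )
        if [a for _, a, _ in spans] != [0] + [b for _, _, b in spans[:-1]] or spans[-1][
            2
        ] != values.shape[2]:
            raise ValueError("channel_spans must partition the channel axis")
        object.__setattr__(self, "channel_spans", spans)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> int:
        return self.values.shape[2]

    def save(self, path) -> None:
        """NPZ container plus a JSON sidecar carrying tag and shape."""
        np.savez(path, values=self.values)
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(
                {"source_tag": self.source_tag, "shape": list(self.values.shape)}, fh
            )

    @classmethod
    def load(cls, path) -> "FeatureMapStack":
        values = np.load(str(path))["values"]
        tag = ""
        try:
            with open(str(path) + ".json") as fh:
                tag = json.load(fh).get("source_tag", "")
        except FileNotFoundError:
            pass
        return cls(values=values, source_tag=tag)


@dataclass(frozen=True)
class FusedFeatureVector:
    """Pooled fusion output with per-source channel provenance."""

    values: np.ndarray
    provenance: tuple[tuple[str, int, int], ...] = field(default=())
    # provenance spans (tag, start, stop) partition the vector

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", values)
        spans = tuple((str(t), int(a), int(b)) for t, a, b in self.provenance)
        object.__setattr__(self, "provenance", spans)
        if spans:
            edges = [0] + [b for _, _, b in spans]
            starts = [a for _, a, _ in spans]
            if starts != edges[:-1] or edges[-1] != values.size:
                raise ValueError("provenance spans must partition the vector")


def _resample_plane(plane: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    in_h, in_w = plane.shape
    # half-pixel sample centers, clamped to the source grid
    ys = (np.arange(out_h) + 0.5) * (in_h / out_h) - 0.5
    xs = (np.arange(out_w) + 0.5) * (in_w / out_w) - 0.5
    ys = np.clip(ys, 0.0, in_h - 1.0)
    xs = np.clip(xs, 0.0, in_w - 1.0)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, in_h - 1)
    x1 = np.minimum(x0 + 1, in_w - 1)
    wy = (ys - y0)[:, None]
    wx = (xs - x0)[None, :]
    top = plane[np.ix_(y0, x0)] * (1 - wx) + plane[np.ix_(y0, x1)] * wx
    bot = plane[np.ix_(y1, x0)] * (1 - wx) + plane[np.ix_(y1, x1)] * wx
    return top * (1 - wy) + bot * wy


def bilinear_resample(stack: FeatureMapStack, out_h: int, out_w: int) -> FeatureMapStack:
    """Per-channel bilinear resampling to (out_h, out_w)."""
    if out_h < 1 or out_w < 1:
        raise ValueError(f"target size must be positive, got {(out_h, out_w)}")
    if (out_h, out_w) == (stack.height, stack.width):
        return stack
    out = np.empty((out_h, out_w, stack.channels))
    for c in range(stack.channels):
        out[:, :, c] = _resample_plane(stack.values[:, :, c], out_h, out_w)
    return FeatureMapStack(
        values=out, source_tag=stack.source_tag, channel_spans=stack.channel_spans
    )


def fuse_maps(maps: Sequence[FeatureMapStack]) -> FeatureMapStack:
    """Align all maps to the minimum spatial size and concatenate channels.

    Input order is preserved in the channel order of the output; the fused
    tag records the contributing layer tags.
    """
    if len(maps) == 0:
        raise ValueError("fuse_maps needs at least one feature map")
    if len(maps) == 1:
        return maps[0]
    target_h = min(m.height for m in maps)
    target_w = min(m.width for m in maps)
    resampled = [bilinear_resample(m, target_h, target_w) for m in maps]
    values = np.concatenate([m.values for m in resampled], axis=2)
    tag = "+".join(m.source_tag or "?" for m in maps)
    spans: list[tuple[str, int, int]] = []
    offset = 0
    for m in resampled:
        for t, a, b in m.channel_spans:
            spans.append((t, offset + a, offset + b))
        offset += m.channels
    return FeatureMapStack(values=values, source_tag=tag, channel_spans=tuple(spans))


def two_level_fuse(
    a: FeatureMapStack, b: FeatureMapStack, c: FeatureMapStack
) -> FeatureMapStack:
    """First-level fusion of (a, b), re-fused with c at the second level.

    Channel order is a-channels, b-channels, c-channels, matching a flat
    three-way fusion whenever the intermediate minimum size coincides with
    the global one.
    """
    return fuse_maps([fuse_maps([a, b]), c])


def pool_to_vector(stack: FeatureMapStack) -> FusedFeatureVector:
    """Global average pooling per channel, with provenance spans."""
    values = stack.values.mean(axis=(0, 1))
    return FusedFeatureVector(values=values, provenance=stack.channel_spans)
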