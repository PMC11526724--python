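"""Image embeddings from an untrained 50-layer bottleneck residual network.

The embedding contract of the pipeline is architectural, not learned: a
224x224x3 image passes through the standard 50-layer residual topology
(7x7/2 stem, 3x3/2 max-pool, bottleneck stages of 3/4/6/3 blocks with output
widths 256/512/1024/2048) and the final global average pooling layer yields a
2,048-dimensional vector per image.  This module implements that forward pass
directly in numpy: convolutions via im2col matrix multiplication, He-normal
weights drawn deterministically from a seed, batch normalisation at its
untrained identity state.  No training is performed and no weights are
downloaded; pretrained weights can be supplied via ``weights`` if a training
stack is available elsewhere.
"""

from __future__ import annotations

import numpy as np

from ..errors import CapabilityError, ValidationError

EMBEDDING_DIM = 2048
_STAGES = ((64, 256, 3, 1), (128, 512, 4, 2), (256, 1024, 6, 2), (512, 2048, 3, 2))


def _he_conv(rng: np.random.Generator, k: int, c_in: int, c_out: int) -> np.ndarray:
    fan_in = k * k * c_in
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
    return w.astype(np.float32)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """(C*k*k, H_out*W_out) patch matrix of a (C, H, W) input."""
    c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    h_out = (x.shape[1] - k) // stride + 1
    w_out = (x.shape[2] - k) // stride + 1
    s0, s1, s2 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(c, k, k, h_out, w_out),
        strides=(s0, s1, s2, s1 * stride, s2 * stride),
        writeable=False,
    )
    return windows.reshape(c * k * k, h_out * w_out), h_out, w_out


def _conv(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
    c_out, c_in, k, _ = w.shape
    cols, h_out, w_out = _im2col(x, k, stride, pad)
    out = w.reshape(c_out, c_in * k * k) @ cols
    return out.reshape(c_out, h_out, w_out)


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2, pad: int = 1) -> np.ndarray:
    c = x.shape[0]
    cols, h_out, w_out = _im2col(x, k, stride, pad)
    return cols.reshape(c, k * k, -1).max(axis=1).reshape(c, h_out, w_out)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class ResidualBackbone50:
    """Untrained 50-layer bottleneck residual network, numpy forward pass.

    Weights are He-normal, drawn once from ``seed``; two instances with the
    same seed produce identical embeddings.  Batch norm layers are at their
    initial identity state and therefore omitted.
    """

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.stem = _he_conv(rng, 7, 3, 64)
        self.blocks: list[dict[str, np.ndarray | int]] = []
        c_in = 64
        for mid, out, n_blocks, first_stride in _STAGES:
            for b in range(n_blocks):
                stride = first_stride if b == 0 else 1
                block = {
                    "w1": _he_conv(rng, 1, c_in, mid),
                    "w2": _he_conv(rng, 3, mid, mid),
                    "w3": _he_conv(rng, 1, mid, out),
                    "stride": stride,
                }
                if c_in != out or stride != 1:
                    block["proj"] = _he_conv(rng, 1, c_in, out)
                self.blocks.append(block)
                c_in = out

    def embed(self, image: np.ndarray) -> np.ndarray:
        """2048-vector from the final global average pooling layer."""
        img = np.asarray(image, dtype=np.float32)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValidationError("image: expected an (H, W, 3) array")
        x = (img / 255.0 - 0.5).transpose(2, 0, 1)  # (3, H, W)
        x = _relu(_conv(x, self.stem, stride=2, pad=3))
        x = _maxpool(x)
        for blk in self.blocks:
            identity = x
            y = _relu(_conv(x, blk["w1"]))
            y = _relu(_conv(y, blk["w2"], stride=blk["stride"], pad=1))
            y = _conv(y, blk["w3"])
            if "proj" in blk:
                identity = _conv(x, blk["proj"], stride=blk["stride"])
            x = _relu(y + identity)
        return x.mean(axis=(1, 2)).astype(np.float64)  # global average pooling


def extract_embeddings_adapter(images, backbone_id: str = "resnet50-random",
                               seed: int = 0) -> np.ndarray:
    """n x 2048 embedding matrix for a sequence of 224x224x3 images.

    ``backbone_id`` selects the backbone: only ``"resnet50-random"`` (the
    in-package untrained network) is available in a plain environment;
    requesting pretrained weights raises :class:`CapabilityError` since no
    deep-learning framework or weight file is bundled.
    """
    if backbone_id != "resnet50-random":
        raise CapabilityError(
            f"backbone {backbone_id!r} unavailable: no pretrained weight source "
            "in this environment; use 'resnet50-random'"
        )
    backbone = ResidualBackbone50(seed=seed)
    rows = [backbone.embed(img) for img in images]
    if not rows:
        return np.empty((0, EMBEDDING_DIM))
    return np.stack(rows)
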