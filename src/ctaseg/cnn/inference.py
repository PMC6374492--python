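"""Tiled whole-volume inference producing lesion probability maps."""

from __future__ import annotations

import numpy as np

from ..grid import BinaryMask, GridMismatchError, ImageVolume, ProbabilityMap
from .network import MultiScalePatchNet, NetworkConfig
from .sampling import SampleableCase, extract_patches


def _tiles_for_mask(mask: np.ndarray, out: int):
    """Centres of disjoint output tiles covering the mask bounding box."""
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    centers = []
    for sx in range(lo[0], hi[0], out):
        for sy in range(lo[1], hi[1], out):
            for sz in range(lo[2], hi[2], out):
                centers.append((sx + out // 2, sy + out // 2, sz + out // 2))
    return centers


def predict(
    net: MultiScalePatchNet,
    channels: list[ImageVolume],
    mask: BinaryMask,
    batch_tiles: int = 16,
) -> ProbabilityMap:
    """Per-voxel lesion probabilities over the intracranial mask.

    The output grid is covered by disjoint tiles (so stitching is seam-free
    by construction); probabilities outside the mask are exactly zero.
    Raises :class:`GridMismatchError` naming the offending channel on any
    grid disagreement.
    """
    cfg: NetworkConfig = net.config
    if len(channels) != cfg.n_input_channels:
        raise GridMismatchError(
            f"model expects {cfg.n_input_channels} channel(s), got {len(channels)}"
        )
    ref = channels[0]
    for i, ch in enumerate(channels[1:], start=2):
        if not ref.grid_congruent(ch):
            raise GridMismatchError(f"channel {i} is not grid-congruent with channel 1")
        ref.require_congruent(mask.volume, "intracranial mask")

    # reuse the sampling plumbing: fabricate a minimal preprocessed view
    class _View:
        case_id = "predict"

        def __init__(self):
            self.channels = {f"ch{i}": ch for i, ch in enumerate(channels)}
            self.channels["cta"] = channels[0]
            self.lesion_mask = BinaryMask.from_array(np.zeros(ref.shape, dtype=np.uint8), ref)
            self.brain_mask = mask

    names = ["cta"] + [f"ch{i}" for i in range(1, len(channels))]
    scase = SampleableCase.from_preprocessed(_View(), names, cfg)

    out = cfg.output_patch
    prob = np.zeros(ref.shape)
    centers = _tiles_for_mask(mask.as_bool(), out)
    for i in range(0, len(centers), batch_tiles):
        chunk = centers[i : i + batch_tiles]
        xs, cs = [], []
        for c in chunk:
            xn, xc, _ = extract_patches(scase, np.asarray(c), cfg)
            xs.append(xn)
            cs.append(xc)
        p = net.forward(np.stack(xs), np.stack(cs) if cs[0] is not None else None)
        for c, pk in zip(chunk, p[:, 1]):
            sl = tuple(
                slice(ci - out // 2, ci - out // 2 + out) for ci in c
            )
            # tiles may overhang the volume near the high edge; clip
            clipped = tuple(slice(s.start, min(s.stop, n)) for s, n in zip(sl, ref.shape))
            sub = tuple(slice(0, cl.stop - cl.start) for cl in clipped)
            prob[clipped] = pk[sub]
    prob *= mask.as_bool()
    np.clip(prob, 0.0, 1.0, out=prob)
    return ProbabilityMap(ref.with_values(prob), mask)
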