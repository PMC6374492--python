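"""Patch extraction, training-batch sampling and reflection augmentation.

A training example is a pair of co-centred windows — the normal-resolution
patch and the block-averaged context window — plus the ground-truth labels on
the network's output grid.  Patches are drawn only from within the brain
mask; a configurable fraction is centred on lesion-positive voxels to counter
the extreme class imbalance of small unilateral lesions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..grid import GridMismatchError
from .network import NetworkConfig

logger = logging.getLogger(__name__)

CHANNEL_SETS = {
    "cta": ("cta",),
    "cta+flip": ("cta", "hemi"),
    "cta+flip+ncct": ("cta", "hemi", "ncct"),
}


def pad_margin(config: NetworkConfig) -> int:
    """Voxels of padding needed so any in-volume centre has full windows."""
    half_normal = config.input_patch // 2
    half_context = (config.context_extent + 1) // 2 if config.n_pathways == 2 else 0
    return max(half_normal, half_context) + 1


@dataclass
class SampleableCase:
    """A preprocessed case unpacked into padded arrays ready for windowing."""

    case_id: str
    channels: np.ndarray      # (C, X+2M, Y+2M, Z+2M), edge-padded
    labels: np.ndarray        # (X+2M, ...), zero-padded {0,1}
    mask: np.ndarray          # (X+2M, ...), zero-padded bool
    margin: int
    channel_names: tuple[str, ...]
    brain_coords: np.ndarray  # (N, 3) unpadded voxel indices
    lesion_coords: np.ndarray  # (K, 3)

    @classmethod
    def from_preprocessed(cls, pcase, channel_names, net_config: NetworkConfig) -> "SampleableCase":
        vols = []
        ref = pcase.channels["cta"]
        for name in channel_names:
            if name not in pcase.channels:
                raise GridMismatchError(f"case {pcase.case_id} lacks channel {name!r}")
            vol = pcase.channels[name]
            ref.require_congruent(vol, f"channel {name}")
            vols.append(vol.values)
        m = pad_margin(net_config)
        pad3 = [(m, m)] * 3
        stack = np.stack([np.pad(v, pad3, mode="edge") for v in vols]).astype(np.float64)
        labels = np.pad(pcase.lesion_mask.values.astype(np.int64), pad3)
        mask = np.pad(pcase.brain_mask.as_bool(), pad3)
        return cls(
            case_id=pcase.case_id,
            channels=stack,
            labels=labels,
            mask=mask,
            margin=m,
            channel_names=tuple(channel_names),
            brain_coords=np.argwhere(pcase.brain_mask.as_bool()),
            lesion_coords=np.argwhere(pcase.lesion_mask.as_bool()),
        )


def extract_patches(case: SampleableCase, center: np.ndarray, config: NetworkConfig):
    """Windows for one centre voxel (unpadded coordinates).

    Returns ``(x_normal, x_context, labels)`` with shapes
    (C, p, p, p), (C, pc, pc, pc) or None, and (o, o, o).
    """
    c = np.asarray(center) + case.margin
    o, p = config.output_patch, config.input_patch
    n_start = c - p // 2
    sl = tuple(slice(s, s + p) for s in n_start)
    x_normal = case.channels[(slice(None),) + sl]

    x_context = None
    if config.n_pathways == 2:
        f, ci = config.context_downsample_factor, config.context_input
        ext = config.context_extent
        c_start = c - ext // 2
        slc = tuple(slice(s, s + ext) for s in c_start)
        region = case.channels[(slice(None),) + slc]
        x_context = region.reshape(-1, ci, f, ci, f, ci, f).mean(axis=(2, 4, 6))

    l_start = c - o // 2
    sll = tuple(slice(s, s + o) for s in l_start)
    return x_normal, x_context, case.labels[sll]


def augment_reflection(x_normal, x_context, labels, channel_roles, swap_roles: bool = False):
    """Mirror one training example along the left-right axis.

    All channels and the labels are reflected in unison; applying the
    operation twice returns the original example bit-exactly.  Unison
    reflection is already self-consistent for the hemispheric-comparison
    channel: the comparison channel of a mirrored subject is the mirror of
    the original comparison channel.  ``swap_roles`` optionally exchanges the
    primary-CTA and comparison channels on top of the reflection — kept as a
    toggle for experimentation, but off by default because the swap inverts
    the lesion's dark-here/bright-contralateral signature and degrades
    region-level specificity in practice.
    """
    xn = x_normal[:, ::-1].copy()
    xc = x_context[:, ::-1].copy() if x_context is not None else None
    y = labels[::-1].copy()
    roles = list(channel_roles)
    if swap_roles and "cta" in roles and "hemi" in roles:
        i, j = roles.index("cta"), roles.index("hemi")
        for arr in (xn,) if xc is None else (xn, xc):
            arr[[i, j]] = arr[[j, i]]
    return xn, xc, y


def sample_training_batch(
    cases: list[SampleableCase],
    net_config: NetworkConfig,
    rng: np.random.Generator,
    batch_size: int = 10,
    foreground_fraction: float = 0.5,
    augment: bool = True,
    swap_roles: bool = True,
):
    """Draw one mini-batch of (normal, context, label) patch triples.

    Each draw is foreground-centred with probability ``foreground_fraction``
    (falling back to uniform in-mask sampling, with a logged warning, when no
    case carries lesion voxels).
    """
    lesioned = [c for c in cases if len(c.lesion_coords)]
    if foreground_fraction > 0 and not lesioned:
        logger.warning("no lesion voxels in cohort; falling back to uniform in-mask sampling")
    xs, cs, ys = [], [], []
    for _ in range(batch_size):
        fg = bool(lesioned) and rng.random() < foreground_fraction
        if fg:
            case = lesioned[rng.integers(len(lesioned))]
            coords = case.lesion_coords
        else:
            case = cases[rng.integers(len(cases))]
            coords = case.brain_coords
        center = coords[rng.integers(len(coords))]
        xn, xc, y = extract_patches(case, center, net_config)
        if augment and rng.random() < 0.5:
            xn, xc, y = augment_reflection(xn, xc, y, case.channel_names, swap_roles)
        xs.append(xn)
        cs.append(xc)
        ys.append(y)
    x_normal = np.stack(xs)
    x_context = np.stack(cs) if cs[0] is not None else None
    return x_normal, x_context, np.stack(ys)
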