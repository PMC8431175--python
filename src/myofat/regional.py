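"""Lengthwise division of a muscle mask into proximal, middle and distal thirds.

The occupied slice span of the mask along its inferior-superior axis is
partitioned into three contiguous slice intervals whose lengths differ by at
most one slice.  The interval at the annotated proximal end becomes the
proximal section.  Division is by slice count of the span, not by voxel-count
terciles: masks are drawn slice-wise, so anatomical length is slice extent,
and empty gap slices inside the span still count toward length.

Remainder rule for a span of ``3q + r`` slices: ``r == 1`` gives the extra
slice to the middle section (q / q+1 / q); ``r == 2`` gives one each to
proximal and distal (q+1 / q / q+1).  The rule is symmetric, so reversing the
proximal annotation swaps proximal and distal and leaves the middle unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masks import MuscleMask

__all__ = ["RegionalSplit", "split_thirds", "SECTION_NAMES"]

SECTION_NAMES = ("proximal", "middle", "distal")


@dataclass(frozen=True)
class RegionalSplit:
    """Three disjoint section masks whose union is the input mask.

    ``slice_bounds`` maps each section name to its half-open slice-index
    interval ``(start, stop)`` along the mask's inferior-superior axis, in
    array coordinates.
    """

    proximal: MuscleMask
    middle: MuscleMask
    distal: MuscleMask
    slice_bounds: dict[str, tuple[int, int]]

    def sections(self) -> dict[str, MuscleMask]:
        return {"proximal": self.proximal, "middle": self.middle, "distal": self.distal}


def _third_lengths(span: int) -> tuple[int, int, int]:
    """Partition ``span`` slices into three lengths differing by at most 1."""
    q, r = divmod(span, 3)
    if r == 0:
        return q, q, q
    if r == 1:
        return q, q + 1, q
    return q + 1, q, q + 1


def split_thirds(mask: MuscleMask, remainder_rule: str = "middle") -> RegionalSplit:
    """Split a muscle mask lengthwise into equal thirds.

    Parameters
    ----------
    mask : MuscleMask
        Must occupy at least 3 slices along its annotated axis.
    remainder_rule : {"middle", "proximal", "distal"}
        Where a single leftover slice goes when ``span % 3 == 1``
        (with ``span % 3 == 2`` the two leftover slices always go to the
        outer sections).  Default "middle".

    Returns
    -------
    RegionalSplit
        Sections are pairwise disjoint and their union equals the input
        exactly; every in-mask voxel belongs to exactly one section.
    """
    if remainder_rule not in ("middle", "proximal", "distal"):
        raise ValueError(f"unknown remainder_rule {remainder_rule!r}")
    occupied = mask.occupied_slices()
    if occupied.size == 0:
        raise ValueError("empty mask cannot be split")
    first, last = int(occupied[0]), int(occupied[-1])
    span = last - first + 1
    if span < 3:
        raise ValueError(f"mask spans only {span} slice(s) along axis {mask.axis}; need >= 3")

    lengths = list(_third_lengths(span))
    if span % 3 == 1 and remainder_rule != "middle":
        q = span // 3
        if remainder_rule == "proximal":
            lengths = [q + 1, q, q]
        else:
            lengths = [q, q, q + 1]

    # lengths[0] is the proximal section; lay intervals out from the proximal
    # end of the occupied span.
    if mask.proximal_end == "low":
        starts = np.concatenate([[first], first + np.cumsum(lengths)[:-1]])
        intervals = [(int(s), int(s + l)) for s, l in zip(starts, lengths)]
    else:
        stops = np.concatenate([[last + 1], last + 1 - np.cumsum(lengths)[:-1]])
        intervals = [(int(s - l), int(s)) for s, l in zip(stops, lengths)]

    section_masks = {}
    for name, (start, stop) in zip(SECTION_NAMES, intervals):
        sel = np.zeros(mask.voxels.shape[mask.axis], dtype=bool)
        sel[start:stop] = True
        shape = [1, 1, 1]
        shape[mask.axis] = sel.size
        section_masks[name] = mask.with_voxels(mask.voxels & sel.reshape(shape))

    return RegionalSplit(
        proximal=section_masks["proximal"],
        middle=section_masks["middle"],
        distal=section_masks["distal"],
        slice_bounds={name: iv for name, iv in zip(SECTION_NAMES, intervals)},
    )
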