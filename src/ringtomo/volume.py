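"""Stack per-element slices into a 3-D volume.

Each element of the 128-element array reconstructs one horizontal slice;
stacking them at the 1 mm element pitch gives a volume whose z axis runs
downward from element 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StackingError
from .reconstruct import SliceImage

__all__ = ["Volume", "stack_slices"]


@dataclass(frozen=True)
class Volume:
    """3-D image: voxels indexed (slice, row, col), values in [0, 1]."""

    voxels: np.ndarray
    slice_spacing_mm: float
    pixel_size_mm: float
    elements: tuple[int, ...]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def z_span_mm(self) -> float:
        """Distance between first and last slice planes."""
        return (self.n_slices - 1) * self.slice_spacing_mm

    def slice_z_mm(self, k: int) -> float:
        return (self.elements[k] - 1) * self.slice_spacing_mm


def stack_slices(slices: list[SliceImage], pitch_mm: float = 1.0) -> Volume:
    """Stack slices into a volume, one z-plane per element at z=(element-1)*pitch.

    Slices must share shape and pixel size and have strictly increasing
    element indices; violations raise StackingError naming the offending
    slice.
    """
    if not slices:
        raise StackingError("no slices to stack")
    if pitch_mm <= 0:
        raise StackingError("pitch must be > 0")
    first = slices[0]
    for k, s in enumerate(slices[1:], start=1):
        if s.shape != first.shape:
            raise StackingError(
                f"slice {k} (element {s.element}) has shape {s.shape}, "
                f"expected {first.shape}"
            )
        if s.pixel_size_mm != first.pixel_size_mm:
            raise StackingError(
                f"slice {k} (element {s.element}) has pixel size "
                f"{s.pixel_size_mm}, expected {first.pixel_size_mm}"
            )
    elements = [s.element for s in slices]
    if any(b <= a for a, b in zip(elements, elements[1:])):
        raise StackingError(
            f"element indices must be strictly increasing, got {elements}"
        )
    return Volume(
        voxels=np.stack([s.pixels for s in slices], axis=0),
        slice_spacing_mm=pitch_mm,
        pixel_size_mm=first.pixel_size_mm,
        elements=tuple(elements),
    )
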