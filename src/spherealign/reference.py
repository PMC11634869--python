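"""Architecture arithmetic for the CIFAR-style ResNet feature source.

The activity vectors this package was designed around come from the second
residual stage of a CIFAR ResNet-20 (He et al. style: widths 16/32/64 over
three stages, spatial maps 32/16/8 on a 32x32 input, downsampling by
stride-2 at the first block of stages 2 and 3).  Nothing here touches
weights — these are pure shape computations, used to size synthetic data
and to document where the 8,192-dimensional flattened feature vector and
its random subsamples (4,096 / 2,048 / 1,024) come from.
"""

from __future__ import annotations

__all__ = ["cifar_resnet_stage_shapes", "resnet20_stage2_flat_dim"]

_STAGE_WIDTHS = (16, 32, 64)


def cifar_resnet_stage_shapes(input_hw: int = 32) -> list[tuple[int, int, int]]:
    """(channels, height, width) after each of the three residual stages.

    Stage 1 keeps the input resolution; stages 2 and 3 halve it with a
    stride-2 first block, as in the standard CIFAR ResNet family
    (ResNet-20/32/44/...).
    """
    shapes = []
    hw = input_hw
    for i, ch in enumerate(_STAGE_WIDTHS):
        if i > 0:
            hw = (hw + 1) // 2  # stride-2 conv with padding 1 on 3x3 kernel
        shapes.append((ch, hw, hw))
    return shapes


def resnet20_stage2_flat_dim(input_hw: int = 32) -> int:
    """Flattened dimensionality of the second-stage output (c * h * w)."""
    c, h, w = cifar_resnet_stage_shapes(input_hw)[1]
    return c * h * w
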