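"""Model architecture configuration shared by the network modules."""

from __future__ import annotations

from dataclasses import dataclass

STRIDES = (8, 16, 32, 64, 128)  # pyramid levels P3..P7 / F3..F7


@dataclass(frozen=True)
class ModelConfig:
    """Architecture knobs for the dual-path model.

    ``profile`` selects the backbone: ``resnet50`` (bottleneck stages
    [3,4,6,3], pyramid at 256 channels) or ``tiny`` (3-stage residual
    backbone with channels (64,128,256) and a 64-channel pyramid, sized for
    CPU-scale experiments).  ``k``/``n`` are the basis-decoder output
    channels and conv-tower depth; ``attention_size`` is the M of the M x M
    per-instance attention maps; ``se_ratio`` the squeeze-excitation
    reduction.
    """

    profile: str = "resnet50"
    k: int = 4
    n: int = 3
    se_ratio: int = 16
    attention_size: int = 7  # M
    roi_size: int = 14  # R
    topk_per_level: int = 100  # d, a declared choice (not printed anywhere)
    nms_threshold: float = 0.3
    box_vote_iou: float = 0.4  # score-weighted box voting; 0 disables
    max_instances: int = 64  # slots in the length vector
    mask_threshold: float = 0.5
    basis_source: str = "F3"  # or "B": feature fed to RoIAlign
    attend_mode: str = "single"  # one M x M map per instance
    center_sample_radius: float = 1.5  # in strides, positive-sampling radius

    def __post_init__(self):
        if self.profile not in ("resnet50", "tiny"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.n < 1 or self.k < 1:
            raise ValueError("decoder depth n and basis count k must be >= 1")
        if self.basis_source not in ("F3", "B"):
            raise ValueError("basis_source must be 'F3' or 'B'")
        if self.attend_mode not in ("single", "per_basis"):
            raise ValueError("attend_mode must be 'single' or 'per_basis'")

    @property
    def fpn_channels(self) -> int:
        return 256 if self.profile == "resnet50" else 64

    @property
    def backbone_channels(self) -> tuple:
        return (512, 1024, 2048) if self.profile == "resnet50" else (64, 128, 256)

    @property
    def head_convs(self) -> int:
        return 4 if self.profile == "resnet50" else 2

    @property
    def regress_ranges(self) -> tuple:
        """Per-level FCOS box-size ranges (max ltrb distance, px)."""
        if self.profile == "resnet50":
            return ((0, 64), (64, 128), (128, 256), (256, 512), (512, 1e8))
        return ((0, 24), (24, 48), (48, 96), (96, 192), (192, 1e8))

    @staticmethod
    def tiny(**overrides) -> "ModelConfig":
        return ModelConfig(profile="tiny", **overrides)
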