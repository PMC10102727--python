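"""Analysis configuration shared by the pipeline and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .exceptions import ValidationError


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the irreversibility pipeline.

    Defaults reproduce the reference parameters: shift T=1, 90-timepoint
    windows with 85-timepoint overlap, binarization threshold 0.01.
    """

    shift: int = 1
    window_length: int = 90
    overlap: int = 85
    alpha: float = 0.01
    estimator: str = "segment_normalized"
    include_final_window: bool = False
    include_diagonal: bool = True
    zero_variance_policy: str = "error"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValidationError("shift must be non-negative")
        if not 0 <= self.overlap < self.window_length:
            raise ValidationError("overlap must be in [0, window_length)")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.estimator not in ("segment_normalized", "full_window"):
            raise ValidationError(f"unknown estimator {self.estimator!r}")
        if self.zero_variance_policy not in ("error", "zero"):
            raise ValidationError(
                f"unknown zero_variance_policy {self.zero_variance_policy!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)
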