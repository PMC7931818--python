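"""Tunable parameters of the deconvolution pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["SCORING_METHODS", "DeconvolutionConfig"]

#: Recognised signature-scoring methods (canonical lower-case names).
SCORING_METHODS = ("entropy", "meanrat", "meandiff", "zscore", "fsrat", "fsdiff")

MAX_NUM_SIGS = 10_000


@dataclass
class DeconvolutionConfig:
    """The four parameters that shape signature selection and regression.

    Attributes
    ----------
    sig_method
        Gene-scoring method; ``"entropy"`` (the default) selects the
        genes whose expression is most concentrated in one cell type.
    num_sigs
        Mean number of signature genes per cell type; the total budget
        is ``num_sigs * K`` for K reference cell types.
    min_sigs
        Minimum signatures guaranteed per cell type; defaults to
        ``num_sigs``, in which case selection is exactly per-type top-N
        and no global fill occurs.
    row_scale_p
        Row-scaling exponent in [0, 1]. 0 maps every signature-gene row
        onto [0, 1] (the strongest equalization); 1 preserves each
        row's magnitude.
    seed
        Seed for any randomized helper; the core pipeline itself is
        deterministic.
    """

    sig_method: str = "entropy"
    num_sigs: int = 50
    min_sigs: int | None = None
    row_scale_p: float = 0.0
    seed: int = 0
    collapse_strategy: str = field(default="max_mean", repr=False)

    def __post_init__(self) -> None:
        method = str(self.sig_method).lower()
        if method not in SCORING_METHODS:
            raise ValueError(
                f"unknown sig_method {self.sig_method!r}; "
                f"choose from {SCORING_METHODS}"
            )
        self.sig_method = method
        if not 1 <= int(self.num_sigs) <= MAX_NUM_SIGS:
            raise ValueError(f"num_sigs must be in [1, {MAX_NUM_SIGS}]")
        self.num_sigs = int(self.num_sigs)
        if self.min_sigs is None:
            self.min_sigs = self.num_sigs
        self.min_sigs = int(self.min_sigs)
        if not 1 <= self.min_sigs <= self.num_sigs:
            raise ValueError("min_sigs must satisfy 1 <= min_sigs <= num_sigs")
        self.row_scale_p = float(self.row_scale_p)
        if not 0.0 <= self.row_scale_p <= 1.0:
            raise ValueError("row_scale_p must lie in [0, 1]")
        self.seed = int(self.seed)

    def to_dict(self) -> dict:
        return {
            "sig_method": self.sig_method,
            "num_sigs": self.num_sigs,
            "min_sigs": self.min_sigs,
            "row_scale_p": self.row_scale_p,
            "seed": self.seed,
        }
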