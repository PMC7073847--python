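"""Run configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Knobs of the differential-network pipeline.

    alpha0          nominal FDR level for edge calling, in (0, 1)
    method          node-wise estimator: "lasso" or "dantzig"
    gram_source     "adjusted_spearman" (rank-based, default) or "imputed"
    n_lambdas       points on the AIC tuning grid (>= 2)
    refit           OLS refit on each candidate's support before AIC scoring
    lambda_min_ratio  lower end of the lambda grid as a fraction of lambda_max
    delta_override  Winsorization level override; None uses the n-based rule
    seed            seed recorded with run metadata
    weights         weights of the chi-square mixture for K > 2 (None -> all 1)
    output_dir      where CLI commands write artifacts
    """

    alpha0: float = 0.05
    method: str = "lasso"
    gram_source: str = "adjusted_spearman"
    n_lambdas: int = 20
    refit: bool = True
    lambda_min_ratio: float = 0.25
    delta_override: float | None = None
    seed: int = 0
    weights: list[float] | None = None
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha0 < 1.0:
            raise ValueError("alpha0 must lie in (0, 1)")
        if self.method not in ("lasso", "dantzig"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.gram_source not in ("imputed", "adjusted_spearman"):
            raise ValueError(f"unknown gram source {self.gram_source!r}")
        if self.n_lambdas < 2:
            raise ValueError("n_lambdas must be >= 2")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))
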