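"""Shared result container for all normalization methods."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .data import FeatureMatrix


@dataclass
class NormalizationResult:
    """A normalized matrix plus everything needed to reproduce it.

    ``factors`` holds the per-sample scale/offset (column-scaling methods),
    per-feature statistics (pretreatment), or fitted drift parameters /
    curves (order-based methods). ``parameters`` echoes every option the
    method resolved, for the reproducibility sidecar.
    """

    matrix: FeatureMatrix
    factors: pd.DataFrame | None
    method_tag: str
    parameters: dict[str, Any] = field(default_factory=dict)
    retained_feature_ids: list[str] | None = None
    failed_features: list[str] = field(default_factory=list)
    extras: dict[str, Any] = field(default_factory=dict)

    def write(self, matrix_path, factors_path=None, sep: str = "\t") -> None:
        self.matrix.write(matrix_path, sep=sep)
        if factors_path is not None and self.factors is not None:
            self.factors.to_csv(factors_path, sep=sep, index=False)
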