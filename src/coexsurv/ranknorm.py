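"""Per-sample percentile rank transform on the 0-100 scale.

Within each sample (column), a probe's rank is 100 times the fraction of
probes in that sample with strictly lower measured expression: a rank of 55
means 55 per cent of the sample's probes have lower values.  With N probes
the attainable ranks are {0, 100/N, ..., 100(N-1)/N}, so every rank lies in
[0, 100).  Ties share a rank.  Ranking is applied over all probes of the
matrix as loaded, before any probe collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .readwrite import ExpressionMatrix

__all__ = ["RankMatrix", "rank_transform"]

TIE_POLICIES = ("strict_lower", "midrank")


@dataclass(frozen=True)
class RankMatrix:
    """Probe x sample matrix of per-sample percentile ranks in [0, 100)."""

    data: pd.DataFrame

    def __post_init__(self):
        vals = self.data.to_numpy(dtype=float)
        if ((vals < 0) | (vals >= 100)).any():
            raise ValidationError("rank values must lie in [0, 100)")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def as_expression_matrix(self) -> ExpressionMatrix:
        """View the ranks as a plain expression matrix (for probe collapsing
        and TSV serialization, which share the ExpressionMatrix dialect)."""
        return ExpressionMatrix(self.data)


def rank_transform(m: ExpressionMatrix, tie_policy: str = "strict_lower") -> RankMatrix:
    """Transform each sample's values into percentile ranks on [0, 100).

    tie_policy ``strict_lower`` (default): rank = 100 * #{strictly lower}/N,
    tied values sharing the count of the group's minimum.  ``midrank``:
    tied values receive the mean of the ranks they would occupy.
    """
    if tie_policy not in TIE_POLICIES:
        raise ValidationError(f"unknown tie policy {tie_policy!r}")
    n_probes = m.shape[0]
    if n_probes < 2:
        raise ValidationError("rank transform needs at least 2 probes per sample")
    method = "min" if tie_policy == "strict_lower" else "average"
    # rankdata 'min' gives 1 + #{strictly lower}; 'average' the midrank.
    r = rankdata(m.values, method=method, axis=0)
    ranks = (r - 1.0) * (100.0 / n_probes)
    return RankMatrix(pd.DataFrame(ranks, index=m.data.index, columns=m.data.columns))
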