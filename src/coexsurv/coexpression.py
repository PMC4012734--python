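"""Pearson coexpression of two gene profiles.

The pipeline's objective quantity: the product-moment correlation of two
genes' rank profiles across a sample set.  By convention correlations are
computed on rank-transformed values; correlating raw intensities is possible
but must be requested explicitly by extracting profiles from an
untransformed matrix.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

import numpy as np

from .errors import CoexsurvError, ValidationError, ZeroVarianceError

__all__ = ["GeneProfile", "extract_profile", "pearson"]

MIN_SAMPLES = 3  # smallest cohort with a meaningful correlation


@dataclass(frozen=True)
class GeneProfile:
    """One gene's expression (or rank) values over an ordered sample list."""

    gene: str
    sample_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if len(vals) != len(self.sample_ids):
            raise ValidationError(
                f"profile {self.gene!r}: {len(vals)} values for "
                f"{len(self.sample_ids)} samples"
            )
        if not np.isfinite(vals).all():
            raise ValidationError(f"profile {self.gene!r}: non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    def restrict(self, sample_ids) -> "GeneProfile":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"profile {self.gene!r}: unknown sample(s) {missing}")
        idx = [index[s] for s in sample_ids]
        return GeneProfile(self.gene, tuple(sample_ids), self.values[idx])


def extract_profile(matrix, gene: str) -> GeneProfile:
    """Pull one gene's row out of a (rank or expression) matrix as a profile.

    An absent gene raises an error naming near-matches, so that e.g. asking
    for "TP63" in a matrix whose row is labelled "p63" is diagnosable.
    """
    index = list(matrix.data.index)
    if gene not in matrix.data.index:
        lowered = {str(g).lower(): g for g in index}
        candidates = []
        if gene.lower() in lowered:
            candidates.append(lowered[gene.lower()])
        # alias-style near misses ("TP63" vs "p63"): case-insensitive containment
        candidates += [
            g for g in index
            if g not in candidates
            and (gene.lower() in str(g).lower() or str(g).lower() in gene.lower())
        ]
        candidates += [
            c for c in difflib.get_close_matches(gene, [str(g) for g in index], n=5)
            if c not in candidates
        ]
        hint = f"; close matches: {candidates}" if candidates else ""
        raise ValidationError(f"gene {gene!r} not in matrix{hint}")
    return GeneProfile(gene, tuple(matrix.data.columns), matrix.data.loc[gene].to_numpy(dtype=float))


def _pearson_values(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.dot(xc, xc))
    sy = float(np.dot(yc, yc))
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("zero variance in correlation input")
    r = float(np.dot(xc, yc) / np.sqrt(sx * sy))
    return max(-1.0, min(1.0, r))


def pearson(x: GeneProfile, y: GeneProfile, subset=None) -> float:
    """Pearson correlation of two aligned profiles over *subset* (default all).

    Raises on a subset smaller than three samples or on a constant vector —
    never returns a silent NaN.
    """
    if x.sample_ids != y.sample_ids:
        raise ValidationError("profiles are not aligned on the same samples")
    if subset is None:
        xv, yv = x.values, y.values
        n = len(xv)
    else:
        wanted = set(subset)
        idx = [i for i, s in enumerate(x.sample_ids) if s in wanted]
        n = len(idx)
        xv, yv = x.values[idx], y.values[idx]
    if n < MIN_SAMPLES:
        raise CoexsurvError(f"cohort too small for correlation (n={n} < {MIN_SAMPLES})")
    return _pearson_values(xv, yv)
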