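"""Synthetic expression matrices with linked survival tables.

The generator emulates the structure the analysis assumes: a pair of focal
genes whose correlation holds only in a planted subpopulation (the
"interaction" members), a background of mutually independent probes, and
exponential survival times under a proportional-hazards model in which a
designated group (interaction members, high expressers of gene A, or
nobody) carries a hazard ratio.  Censoring is independent exponential.
Everything is reproducible from a single seed; each stage draws from its
own deterministically spawned substream.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .readwrite import ExpressionMatrix, SurvivalTable

__all__ = ["SimConfig", "GroundTruth", "simulate_correlated_pair", "simulate_dataset"]

HAZARD_GROUPS = ("none", "interaction", "high_expression")


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic dataset.

    Expression values are Gaussian with standard deviation ``noise_sigma``
    before rank transformation (ranks make the pipeline marginal-free).
    Survival times are exponential with rate ``baseline_hazard`` times
    ``hazard_ratio`` for members of ``hazard_group``; the default baseline
    ln2/12 puts the median event time at 12 time units (months, say), and
    the default censoring rate ln2/36 censors roughly a quarter of subjects.
    """

    n_samples: int = 200
    n_background_probes: int = 100
    gene_a: str = "TP63"
    gene_b: str = "MMP13"
    f_interaction: float = 0.5
    rho_in: float = 0.9
    rho_out: float = 0.0
    noise_sigma: float = 1.0
    baseline_hazard: float = math.log(2) / 12
    hazard_ratio: float = 1.0
    hazard_group: str = "none"
    censoring_rate: float = math.log(2) / 36
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if self.n_background_probes < 0:
            raise ValidationError("n_background_probes must be >= 0")
        if not 0.0 <= self.f_interaction <= 1.0:
            raise ValidationError("f_interaction must lie in [0, 1]")
        for name in ("rho_in", "rho_out"):
            if abs(getattr(self, name)) > 1.0:
                raise ValidationError(f"{name} must lie in [-1, 1]")
        for name in ("noise_sigma", "baseline_hazard", "hazard_ratio", "censoring_rate"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.hazard_group not in HAZARD_GROUPS:
            raise ValidationError(f"hazard_group must be one of {HAZARD_GROUPS}")
        if self.gene_a == self.gene_b:
            raise ValidationError("focal genes must be distinct")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a simulated dataset, for scoring recovery."""

    interaction_members: frozenset
    labels: pd.DataFrame  # sample_id, group ("interaction" / "background")
    hazard_members: frozenset
    config: SimConfig = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return self.labels.copy()


def simulate_correlated_pair(n: int, rho: float, seed_or_rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw n bivariate-normal pairs with population correlation rho.

    Cholesky construction from two independent standard normals:
    x = z1, y = rho*z1 + sqrt(1-rho^2)*z2.  At rho = +-1 the second vector
    is an exact (anti-)copy of the first.
    """
    if abs(rho) > 1.0:
        raise ValidationError("correlation must lie in [-1, 1]")
    if n < 2:
        raise ValidationError("need n >= 2")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    z = rng.standard_normal((2, n))
    x = z[0]
    y = rho * z[0] + math.sqrt(max(0.0, 1.0 - rho * rho)) * z[1]
    return x, y


def _sample_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def simulate_dataset(cfg: SimConfig) -> tuple[ExpressionMatrix, SurvivalTable, GroundTruth]:
    """Generate (expression matrix, survival table, ground truth) from cfg.

    Exactly ``floor(f_interaction * n_samples)`` randomly chosen samples
    form the interaction subpopulation: their focal pair is drawn at
    ``rho_in``, everyone else's at ``rho_out``.  Background probes are
    independent Gaussians.  Bit-identical given the same config.
    """
    n = cfg.n_samples
    ss = np.random.SeedSequence(cfg.seed)
    rng_assign, rng_focal, rng_bg, rng_surv, rng_cens = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    ids = _sample_ids(n)
    n_inter = int(math.floor(cfg.f_interaction * n))
    inter_idx = np.sort(rng_assign.choice(n, size=n_inter, replace=False))
    is_inter = np.zeros(n, dtype=bool)
    is_inter[inter_idx] = True

    xa = np.empty(n)
    xb = np.empty(n)
    if n_inter >= 2:
        xa[is_inter], xb[is_inter] = simulate_correlated_pair(n_inter, cfg.rho_in, rng_focal)
    elif n_inter:  # a single planted sample: just independent draws
        xa[is_inter], xb[is_inter] = rng_focal.standard_normal(2)
    n_out = n - n_inter
    if n_out >= 2:
        xa[~is_inter], xb[~is_inter] = simulate_correlated_pair(n_out, cfg.rho_out, rng_focal)
    elif n_out:
        xa[~is_inter], xb[~is_inter] = rng_focal.standard_normal(2)
    xa *= cfg.noise_sigma
    xb *= cfg.noise_sigma

    bg = rng_bg.standard_normal((cfg.n_background_probes, n)) * cfg.noise_sigma
    probe_ids = [cfg.gene_a, cfg.gene_b] + [
        f"BG{i + 1:05d}" for i in range(cfg.n_background_probes)
    ]
    values = np.vstack([xa, xb, bg]) if cfg.n_background_probes else np.vstack([xa, xb])
    matrix = ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=ids))

    if cfg.hazard_group == "interaction":
        hazard_flag = is_inter
    elif cfg.hazard_group == "high_expression":
        hazard_flag = xa > np.median(xa)
    else:
        hazard_flag = np.zeros(n, dtype=bool)
    rates = cfg.baseline_hazard * np.where(hazard_flag, cfg.hazard_ratio, 1.0)
    t_event = rng_surv.exponential(1.0 / rates)
    t_cens = rng_cens.exponential(1.0 / cfg.censoring_rate, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = SurvivalTable(
        pd.DataFrame({"sample_id": ids, "time": time, "event": event})
    )

    labels = pd.DataFrame(
        {
            "sample_id": ids,
            "group": np.where(is_inter, "interaction", "background"),
        }
    )
    truth = GroundTruth(
        interaction_members=frozenset(np.array(ids)[is_inter]),
        labels=labels,
        hazard_members=frozenset(np.array(ids)[hazard_flag]),
        config=cfg,
    )
    return matrix, survival, truth
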