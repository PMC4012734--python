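"""End-to-end orchestration of the three analyses.

Three runs mirror the study designs the package supports:

* ``run_coexpr`` — rank-transform, optionally collapse probes, report the
  Pearson coexpression of two genes over all samples.
* ``run_marker_survival`` — split samples into high/low expressers of one
  gene at a quantile cutoff and compare their survival (KM + log-rank).
* ``run_interaction_survival`` — greedily split samples into a
  correlation-maximized cohort 1 ("interaction") and the removed cohort 2,
  then compare the cohorts' survival.

Each run can write its tabular outputs (TSV) plus a JSON manifest with the
configuration echo and SHA-256 checksums of every written file, sufficient
to replay the run bit-identically.  Stage failures are re-raised with the
stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import greedy_split
from .coexpression import extract_profile, pearson
from .errors import CoexsurvError, StageError
from .ranknorm import rank_transform
from .readwrite import (
    ExpressionMatrix,
    SurvivalTable,
    align_samples,
    collapse_probes,
)
from .survival import (
    compare_partition_survival,
    km_estimate,
    log_rank,
    split_by_expression,
)

log = logging.getLogger(__name__)

__all__ = ["run_coexpr", "run_marker_survival", "run_interaction_survival"]


@contextmanager
def _stage(name: str):
    log.info("stage %s: start", name)
    try:
        yield
    except StageError:
        raise
    except Exception as e:
        raise StageError(name, str(e)) from e
    log.info("stage %s: done", name)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(out_dir, config: dict, frames: dict, extra: dict | None = None):
    if out_dir is None:
        return
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, frame in frames.items():
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False)
        written[name] = _sha256(path)
    manifest = {
        "package": "coexsurv",
        "version": __version__,
        "config": config,
        "outputs": written,
    }
    if extra:
        manifest.update(extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _prepare_ranks(matrix, probe_map, collapse_policy, tie_policy, named_probes):
    """Shared preprocessing: rank over all probes as loaded, then collapse."""
    with _stage("rank"):
        ranks = rank_transform(matrix, tie_policy=tie_policy)
    if probe_map is not None:
        with _stage("collapse"):
            collapsed = collapse_probes(
                ranks.as_expression_matrix(),
                probe_map,
                policy=collapse_policy,
                named_probes=named_probes,
            )
        return collapsed
    return ranks


def run_coexpr(
    matrix: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    *,
    probe_map=None,
    collapse_policy: str = "max_variance",
    named_probes=None,
    tie_policy: str = "strict_lower",
    out_dir=None,
) -> dict:
    """Coexpression of two genes on rank-normalized values over all samples."""
    ranks = _prepare_ranks(matrix, probe_map, collapse_policy, tie_policy, named_probes)
    with _stage("profiles"):
        pa = extract_profile(ranks, gene_a)
        pb = extract_profile(ranks, gene_b)
    with _stage("pearson"):
        r = pearson(pa, pb)
    report = {"gene_a": gene_a, "gene_b": gene_b, "n": len(pa), "r": r}
    _write_outputs(
        out_dir,
        {"mode": "coexpr", "gene_a": gene_a, "gene_b": gene_b,
         "tie_policy": tie_policy, "collapse_policy": collapse_policy},
        {"coexpr_report.tsv": pd.DataFrame([report])},
    )
    return report


def run_marker_survival(
    matrix: ExpressionMatrix,
    survival: SurvivalTable,
    gene: str,
    *,
    cutoff: float = 0.5,
    probe_map=None,
    collapse_policy: str = "max_variance",
    named_probes=None,
    tie_policy: str = "strict_lower",
    out_dir=None,
) -> dict:
    """High/low single-gene survival comparison at a quantile cutoff."""
    with _stage("align"):
        matrix, survival = align_samples(matrix, survival)
    ranks = _prepare_ranks(matrix, probe_map, collapse_policy, tie_policy, named_probes)
    with _stage("profiles"):
        profile = extract_profile(ranks, gene)
    with _stage("split_by_expression"):
        low, high = split_by_expression(profile, survival, cutoff=cutoff)
    with _stage("km"):
        km_low, km_high = km_estimate(low), km_estimate(high)
    with _stage("log_rank"):
        result = log_rank(low, high)
    report = {
        "gene": gene,
        "cutoff": cutoff,
        "n_low": len(low),
        "n_high": len(high),
        "events_low": int(low.events.sum()),
        "events_high": int(high.events.sum()),
        "statistic": result.statistic,
        "p_value": result.p_value,
    }
    _write_outputs(
        out_dir,
        {"mode": "marker_survival", "gene": gene, "cutoff": cutoff,
         "tie_policy": tie_policy},
        {
            "logrank.tsv": pd.DataFrame([report]),
            "km_low.tsv": km_low.to_frame(),
            "km_high.tsv": km_high.to_frame(),
        },
    )
    return report


def run_interaction_survival(
    matrix: ExpressionMatrix,
    survival: SurvivalTable,
    gene_a: str,
    gene_b: str,
    *,
    min_cohort1: int | None = None,
    tol: float = 1e-12,
    method: str = "exact",
    probe_map=None,
    collapse_policy: str = "max_variance",
    named_probes=None,
    tie_policy: str = "strict_lower",
    out_dir=None,
) -> dict:
    """Greedy correlation-maximizing cohort split followed by a survival
    comparison of the two cohorts.

    When the split removes nobody (cohort 2 empty) the survival comparison
    is skipped and reported as such rather than failing the run.
    """
    with _stage("align"):
        matrix, survival = align_samples(matrix, survival)
    ranks = _prepare_ranks(matrix, probe_map, collapse_policy, tie_policy, named_probes)
    with _stage("profiles"):
        pa = extract_profile(ranks, gene_a)
        pb = extract_profile(ranks, gene_b)
    with _stage("greedy_split"):
        partition = greedy_split(pa, pb, min_cohort1=min_cohort1, tol=tol, method=method)
    r2 = np.nan
    if len(partition.cohort2) >= 3:
        try:
            r2 = pearson(pa, pb, subset=set(partition.cohort2))
        except CoexsurvError:
            pass
    report = {
        "gene_a": gene_a,
        "gene_b": gene_b,
        "n_cohort1": len(partition.cohort1),
        "n_cohort2": len(partition.cohort2),
        "r_all": partition.r_initial,
        "r_cohort1": partition.r_final,
        "r_cohort2": r2,
    }
    frames = {
        "partition.tsv": partition.membership_frame(),
        "trace.tsv": partition.trace_frame(),
    }
    if len(partition.cohort2) == 0:
        report.update(statistic=np.nan, p_value=np.nan,
                      note="no second cohort; survival comparison skipped")
        log.warning("interaction-survival: %s", report["note"])
    else:
        with _stage("compare_survival"):
            result = compare_partition_survival(partition, survival)
            km1 = km_estimate(survival.subset(
                [s for s in partition.cohort1 if s in set(survival.sample_ids)]))
            km2 = km_estimate(survival.subset(
                [s for s in partition.cohort2 if s in set(survival.sample_ids)]))
        report.update(statistic=result.statistic, p_value=result.p_value)
        frames["km_cohort1.tsv"] = km1.to_frame()
        frames["km_cohort2.tsv"] = km2.to_frame()
    frames["correlations.tsv"] = pd.DataFrame(
        [
            {"gene_a": gene_a, "gene_b": gene_b, "cohort": "all",
             "n": len(pa), "r": partition.r_initial},
            {"gene_a": gene_a, "gene_b": gene_b, "cohort": "cohort1",
             "n": len(partition.cohort1), "r": partition.r_final},
            {"gene_a": gene_a, "gene_b": gene_b, "cohort": "cohort2",
             "n": len(partition.cohort2), "r": r2},
        ]
    )
    frames["interaction_report.tsv"] = pd.DataFrame([report])
    _write_outputs(
        out_dir,
        {"mode": "interaction_survival", "gene_a": gene_a, "gene_b": gene_b,
         "min_cohort1": partition.params["min_cohort1"], "tol": tol,
         "method": method, "tie_policy": tie_policy},
        frames,
    )
    return report
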