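"""Reading, writing, and validation of expression matrices, survival tables
and probe-to-gene maps.

File dialects
-------------
Expression matrix: TSV, UTF-8, probes in rows and samples in columns
(series-matrix orientation); first header cell empty or ``probe_id``.
Survival table: TSV with header ``sample_id<TAB>time<TAB>event``.
Probe map: two-column TSV ``probe_id<TAB>gene_symbol``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SurvivalTable",
    "ProbeGeneMap",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_survival_table",
    "write_survival_table",
    "read_probe_gene_map",
    "align_samples",
    "collapse_probes",
]


def _check_unique(ids, axis_name: str) -> None:
    ids = list(ids)
    seen, dupes = set(), []
    for i in ids:
        if i in seen and i not in dupes:
            dupes.append(i)
        seen.add(i)
    if dupes:
        raise ValidationError(f"duplicate {axis_name} id(s): {dupes}")
    if any(pd.isna(i) or str(i).strip() == "" for i in ids):
        raise ValidationError(f"missing/empty {axis_name} id")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probe/gene x sample matrix of real-valued expression intensities.

    Wraps a pandas DataFrame whose index holds probe ids and whose columns
    hold sample ids.  Values must be finite floats; identifiers must be
    unique within their axis.
    """

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("empty expression matrix")
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = self._first_non_numeric()
            raise ValidationError(f"non-numeric cell at {bad}")
        if not np.isfinite(vals).all():
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite value at probe {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    def _first_non_numeric(self):
        for c in self.data.columns:
            coerced = pd.to_numeric(self.data[c], errors="coerce")
            bad = coerced.isna() & self.data[c].notna()
            if bad.any():
                probe = self.data.index[bad.to_numpy().argmax()]
                return f"probe {probe!r}, sample {c!r}"
        return "unknown location"

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

    def restrict_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample id(s): {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class SurvivalTable:
    """Per-sample follow-up time (>0) and event indicator (1 = event, 0 = censored)."""

    data: pd.DataFrame  # columns: sample_id, time, event

    def __post_init__(self):
        required = ["sample_id", "time", "event"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"survival table missing column(s): {missing}")
        df = self.data[required].reset_index(drop=True)
        object.__setattr__(self, "data", df)
        _check_unique(df["sample_id"], "sample")
        times = pd.to_numeric(df["time"], errors="coerce")
        if times.isna().any() or not np.isfinite(times).all():
            raise ValidationError("non-numeric or non-finite time value")
        if (times <= 0).any():
            bad = df.loc[times <= 0, "sample_id"].tolist()
            raise ValidationError(f"non-positive time for sample(s): {bad}")
        events = pd.to_numeric(df["event"], errors="coerce")
        if events.isna().any() or not events.isin([0, 1]).all():
            raise ValidationError("event indicator must be 0 or 1")
        df["time"] = times.astype(float)
        df["event"] = events.astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def events(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, sample_ids) -> "SurvivalTable":
        wanted = list(sample_ids)
        df = self.data.set_index("sample_id")
        missing = [s for s in wanted if s not in df.index]
        if missing:
            raise ValidationError(f"sample id(s) absent from survival table: {missing}")
        return SurvivalTable(df.loc[wanted].reset_index())


@dataclass(frozen=True)
class ProbeGeneMap:
    """Many-to-one mapping from probe id to gene symbol."""

    mapping: dict = field(default_factory=dict)  # probe_id -> gene_symbol

    def gene_of(self, probe_id: str) -> str:
        return self.mapping[probe_id]

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.mapping


def read_expression_matrix(
    path,
    *,
    missing: str = "strict",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (probes x samples).

    Parameters
    ----------
    missing:
        ``"strict"`` (default) rejects any NA/non-numeric cell;
        ``"impute_probe_mean"`` replaces NAs by the per-probe mean.
    transpose:
        Set when the file stores samples in rows.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample (header)")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"empty matrix in {path}")
    if transpose:
        df = df.T
    _check_unique(df.index, "probe")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric cell {df.iat[r, c]!r} at probe {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    if num.isna().to_numpy().any():
        if missing == "strict":
            r, c = np.argwhere(num.isna().to_numpy())[0]
            raise ValidationError(
                f"missing value at probe {df.index[r]!r}, sample {df.columns[c]!r} "
                "(strict mode; use missing='impute_probe_mean' to impute)"
            )
        elif missing != "impute_probe_mean":
            raise ValidationError(f"unknown missing policy {missing!r}")
    # pd.to_numeric above only locates bad cells; the final conversion uses
    # the correctly-rounded str->float64 parser so write/read round-trips
    # are bit-exact
    num = df.astype(float)
    if num.isna().to_numpy().any():
        num = num.apply(lambda row: row.fillna(row.mean()), axis=1)
    m = ExpressionMatrix(num)
    log.info("read expression matrix %s: %d probes x %d samples", path, *m.shape)
    return m


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", index_label="probe_id")


def read_survival_table(path) -> SurvivalTable:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    table = SurvivalTable(df)
    log.info("read survival table %s: %d records", path, len(table))
    return table


def write_survival_table(s: SurvivalTable, path) -> None:
    s.data.to_csv(path, sep="\t", index=False)


def read_probe_gene_map(path) -> ProbeGeneMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("probe map needs two columns: probe_id, gene_symbol")
    probe_col, gene_col = df.columns[:2]
    _check_unique(df[probe_col], "probe (map)")
    return ProbeGeneMap(dict(zip(df[probe_col], df[gene_col])))


def align_samples(m: ExpressionMatrix, s: SurvivalTable):
    """Restrict matrix and survival table to their shared samples, in matrix
    column order.  Fewer than two shared ids is a hard error."""
    surv_ids = set(s.sample_ids)
    shared = [c for c in m.sample_ids if c in surv_ids]
    if len(shared) < 2:
        raise ValidationError(
            f"only {len(shared)} sample id(s) shared between matrix and survival table"
        )
    dropped = (len(m.sample_ids) - len(shared)) + (len(s) - len(shared))
    if dropped:
        log.info("align_samples: dropped %d unshared sample id(s)", dropped)
    return m.restrict_samples(shared), s.subset(shared)


def collapse_probes(
    m: ExpressionMatrix,
    pmap: ProbeGeneMap,
    policy: str = "max_variance",
    named_probes=None,
    unmapped: str = "error",
) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene symbol.

    policy:
        ``max_variance`` (default) keeps, per gene, the probe with the largest
        row variance (ties broken by lexicographically smallest probe id);
        ``mean`` averages a gene's probe rows;
        ``named_probe`` keeps exactly the probes listed in *named_probes*.
    """
    if policy not in {"max_variance", "mean", "named_probe"}:
        raise ValidationError(f"unknown collapse policy {policy!r}")
    missing = [p for p in m.probe_ids if p not in pmap]
    if missing:
        if unmapped == "error":
            raise ValidationError(f"probe id(s) absent from map: {missing[:10]}")
        elif unmapped == "drop":
            m = ExpressionMatrix(m.data.drop(index=missing))
        else:
            raise ValidationError(f"unknown unmapped policy {unmapped!r}")

    if policy == "named_probe":
        if not named_probes:
            raise ValidationError("named_probe policy requires named_probes")
        absent = [p for p in named_probes if p not in m.data.index]
        if absent:
            raise ValidationError(f"named probe(s) not in matrix: {absent}")
        rows = m.data.loc[list(named_probes)]
        rows.index = [pmap.gene_of(p) for p in named_probes]
        _check_unique(rows.index, "gene (named probes)")
        return ExpressionMatrix(rows.sort_index())

    genes: dict[str, list[str]] = {}
    for p in m.probe_ids:
        genes.setdefault(pmap.gene_of(p), []).append(p)

    out = {}
    if policy == "mean":
        for g, probes in genes.items():
            out[g] = m.data.loc[probes].mean(axis=0)
    else:  # max_variance
        variances = m.data.var(axis=1, ddof=1)
        for g, probes in genes.items():
            # highest variance wins; lexicographically smallest probe id on ties
            best = min(probes, key=lambda p: (-variances[p], p))
            out[g] = m.data.loc[best]
    frame = pd.DataFrame(out).T.sort_index()
    frame.columns = m.data.columns
    return ExpressionMatrix(frame)
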