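"""Four-step screen for treatment-responsive microRNAs.

The screen works on an 8-sample two-factor design: four breast cancer cell
lines (two HER2-positive, two HER2-negative), each profiled with and without
trastuzumab exposure.  The steps are:

1. quantile-normalize the raw linear intensities and move to log2,
2. keep microRNAs whose signal exceeds an expression floor (log2 > 6) in
   every line, before or after treatment,
3. drop microRNAs that also respond (>1.5-fold either way) in any
   HER2-negative line,
4. rank the survivors by relative fold change (RFC) — the HER2-positive-line
   fold change divided by the geometric mean of the HER2-negative-line fold
   changes — and list those with more than a 1.5-fold up/down response,
   per line and as a cross-line geometric mean.

All fold-change arithmetic is carried out in log2 space; "subtracting the
average negative-line fold change" therefore corresponds to dividing by the
geometric mean on the linear scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import ConfigError, DesignError, FormatError, MetadataError

logger = logging.getLogger(__name__)

#: floor applied to raw linear intensities before log2 (background-subtracted
#: medians can be negative; log2 must stay defined)
INTENSITY_EPS = 1.0

HER2_POSITIVE = "positive"
HER2_NEGATIVE = "negative"
TREATED = "treated"
CONTROL = "control"


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one array sample."""

    sample_id: str
    cell_line: str
    her2_status: str  # "positive" | "negative"
    treatment: str  # "treated" | "control"
    dose_ug_ml: float = 0.0
    hours: float = 0.0

    def __post_init__(self) -> None:
        if self.her2_status not in (HER2_POSITIVE, HER2_NEGATIVE):
            raise ConfigError(f"unknown HER2 status {self.her2_status!r}")
        if self.treatment not in (TREATED, CONTROL):
            raise ConfigError(f"unknown treatment {self.treatment!r}")


@dataclass
class IntensityMatrix:
    """Raw linear feature intensities (features x samples) plus metadata.

    Values are median foreground minus local background, clipped at
    :data:`INTENSITY_EPS` so the log2 transform is defined.
    """

    values: pd.DataFrame  # index: mirna_id, columns: sample_id
    samples: list[SampleMeta]
    n_clipped: int = 0

    def __post_init__(self) -> None:
        ids = list(self.values.index)
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate miRNA identifiers in matrix")
        meta_ids = [s.sample_id for s in self.samples]
        if len(set(meta_ids)) != len(meta_ids):
            raise MetadataError("duplicate sample_id in sample sheet")
        if list(self.values.columns) != meta_ids:
            missing = set(self.values.columns) ^ set(meta_ids)
            raise MetadataError(
                f"matrix columns and sample sheet disagree (difference: {sorted(missing)})"
            )
        if (self.values.values < 0).any():
            raise FormatError("negative intensity survived clipping")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


@dataclass
class NormalizedMatrix:
    """Log2 intensities after (optional) quantile normalization."""

    values: pd.DataFrame
    samples: list[SampleMeta]
    quantile_normalized: bool = True

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    def columns_for(self, cell_line: str, treatment: str) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.cell_line == cell_line and s.treatment == treatment
        ]

    def lines(self, her2_status: str | None = None) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if her2_status is not None and s.her2_status != her2_status:
                continue
            if s.cell_line not in seen:
                seen.append(s.cell_line)
        return seen


@dataclass(frozen=True)
class FoldChangeRecord:
    mirna_id: str
    cell_line: str
    log2_fc: float

    @property
    def fc_linear(self) -> float:
        return float(2.0 ** self.log2_fc)


@dataclass(frozen=True)
class RfcRecord:
    """Relative fold change of one miRNA in one HER2-positive line."""

    mirna_id: str
    cell_line: str
    log2_rfc: float

    @property
    def rfc_linear(self) -> float:
        return float(2.0 ** self.log2_rfc)


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds of the screen; defaults reproduce the published rules."""

    intensity_floor_log2: float = 6.0
    fc_threshold: float = 1.5
    down_threshold: float = 1.0 / 1.5
    expression_rule: str = "either_condition"  # or "both_conditions"

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1.0:
            raise ConfigError("fc_threshold must exceed 1")
        if not 0.0 < self.down_threshold < 1.0:
            raise ConfigError("down_threshold must lie in (0, 1)")
        if self.expression_rule not in ("either_condition", "both_conditions"):
            raise ConfigError(f"unknown expression_rule {self.expression_rule!r}")


@dataclass
class ScreenReport:
    """Full screen output: filter survivors and ranked RFC lists."""

    retained_after_expression_filter: list[str]
    retained_after_negative_exclusion: list[str]
    per_line_up: dict[str, list[RfcRecord]]
    per_line_down: dict[str, list[RfcRecord]]
    mean_up: list[RfcRecord]  # cell_line == "mean"
    mean_down: list[RfcRecord]
    criteria: ScreenCriteria = field(default_factory=ScreenCriteria)

    @property
    def n_expressed(self) -> int:
        return len(self.retained_after_expression_filter)

    @property
    def n_after_exclusion(self) -> int:
        return len(self.retained_after_negative_exclusion)

    def up_set(self) -> set[str]:
        return {r.mirna_id for r in self.mean_up}

    def down_set(self) -> set[str]:
        return {r.mirna_id for r in self.mean_down}

    def to_frame(self, decimals: int = 4) -> pd.DataFrame:
        """Flatten to the report table (rank, mirna, cell_line, direction, rfc)."""
        rows = []
        blocks = [
            *((line, "up", recs) for line, recs in self.per_line_up.items()),
            *((line, "down", recs) for line, recs in self.per_line_down.items()),
            ("mean", "up", self.mean_up),
            ("mean", "down", self.mean_down),
        ]
        for line, direction, recs in blocks:
            for rank, rec in enumerate(recs, start=1):
                rows.append(
                    {
                        "rank": rank,
                        "mirna": rec.mirna_id,
                        "cell_line": line,
                        "direction": direction,
                        "rfc": round(rec.rfc_linear, decimals),
                    }
                )
        return pd.DataFrame(rows, columns=["rank", "mirna", "cell_line", "direction", "rfc"])

    def to_dict(self, decimals: int = 4) -> dict:
        def ser(recs: list[RfcRecord]) -> list[dict]:
            return [
                {"mirna": r.mirna_id, "cell_line": r.cell_line, "rfc": round(r.rfc_linear, decimals)}
                for r in recs
            ]

        return {
            "n_expressed": self.n_expressed,
            "n_after_negative_exclusion": self.n_after_exclusion,
            "retained_after_expression_filter": self.retained_after_expression_filter,
            "retained_after_negative_exclusion": self.retained_after_negative_exclusion,
            "per_line_up": {k: ser(v) for k, v in self.per_line_up.items()},
            "per_line_down": {k: ser(v) for k, v in self.per_line_down.items()},
            "mean_up": ser(self.mean_up),
            "mean_down": ser(self.mean_down),
            "criteria": {
                "intensity_floor_log2": self.criteria.intensity_floor_log2,
                "fc_threshold": self.criteria.fc_threshold,
                "down_threshold": self.criteria.down_threshold,
                "expression_rule": self.criteria.expression_rule,
            },
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sample_sheet(samples_path) -> list[SampleMeta]:
    df = pd.read_csv(samples_path, dtype={"sample_id": str, "cell_line": str})
    required = {"sample_id", "cell_line", "her2_status", "treatment"}
    if not required.issubset(df.columns):
        raise FormatError(f"sample sheet missing columns {sorted(required - set(df.columns))}")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                cell_line=str(row["cell_line"]),
                her2_status=str(row["her2_status"]),
                treatment=str(row["treatment"]),
                dose_ug_ml=float(row.get("dose_ug_ml", 0.0) or 0.0),
                hours=float(row.get("hours", 0.0) or 0.0),
            )
        )
    return metas


def load_expression_matrix(matrix_path, samples_path) -> IntensityMatrix:
    """Read an expression TSV (first column ``mirna_id``) plus sample sheet.

    Raw values at or below zero are clipped to :data:`INTENSITY_EPS`; the
    number of clipped cells is logged and recorded on the matrix.
    """
    df = pd.read_csv(matrix_path, sep="\t")
    if df.columns[0] != "mirna_id":
        raise FormatError("expression matrix must start with a 'mirna_id' column")
    df = df.set_index("mirna_id")
    if df.index.duplicated().any():
        raise FormatError("duplicate miRNA identifiers in matrix")
    metas = read_sample_sheet(samples_path)
    meta_ids = [m.sample_id for m in metas]
    if sorted(df.columns) != sorted(meta_ids):
        raise MetadataError(
            "sample sheet and matrix header disagree: "
            f"matrix={sorted(df.columns)} sheet={sorted(meta_ids)}"
        )
    df = df[meta_ids].astype(float)
    n_clipped = int((df.values < INTENSITY_EPS).sum())
    if n_clipped:
        logger.info("clipped %d intensity cells at eps=%g", n_clipped, INTENSITY_EPS)
        df = df.clip(lower=INTENSITY_EPS)
    return IntensityMatrix(values=df, samples=metas, n_clipped=n_clipped)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a (features x samples) array.

    Every column's values are replaced, rank-wise, by the mean across columns
    of the sorted values; tied values receive the mean of their tied ranks'
    target values, so the result does not depend on tie order.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ConfigError("quantile normalization needs a non-empty 2-D array")
    n, m = values.shape
    if m == 1:
        return values.copy()
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        assigned = target[ranks]
        # average the assigned targets within groups of tied input values
        ser = pd.Series(assigned)
        out[:, j] = ser.groupby(pd.Series(col)).transform("mean").to_numpy()
    return out


def preprocess(matrix: IntensityMatrix) -> NormalizedMatrix:
    """Quantile-normalize raw linear intensities and transform to log2."""
    if matrix.values.empty:
        raise ConfigError("cannot preprocess an empty matrix")
    clipped = matrix.values.clip(lower=INTENSITY_EPS)
    norm = quantile_normalize(clipped.to_numpy())
    log2 = pd.DataFrame(
        np.log2(norm), index=matrix.values.index, columns=matrix.values.columns
    )
    return NormalizedMatrix(values=log2, samples=matrix.samples, quantile_normalized=True)


def _condition_means(norm: NormalizedMatrix, line: str) -> tuple[pd.Series, pd.Series]:
    """Per-miRNA mean log2 for (treated, control) of one line; replicates averaged."""
    t_cols = norm.columns_for(line, TREATED)
    c_cols = norm.columns_for(line, CONTROL)
    if not t_cols or not c_cols:
        raise DesignError(f"line {line!r} is missing a treated or control sample")
    return norm.values[t_cols].mean(axis=1), norm.values[c_cols].mean(axis=1)


# ---------------------------------------------------------------------------
# Screen steps
# ---------------------------------------------------------------------------

def filter_expressed(norm: NormalizedMatrix, criteria: ScreenCriteria | None = None) -> list[str]:
    """Keep miRNAs exceeding the log2 expression floor in every cell line.

    Under the default ``either_condition`` rule a line passes when the larger
    of its treated/control signals is above the floor; under
    ``both_conditions`` both must be.
    """
    criteria = criteria or ScreenCriteria()
    keep = pd.Series(True, index=norm.values.index)
    for line in norm.lines():
        treated, control = _condition_means(norm, line)
        if criteria.expression_rule == "either_condition":
            stat = np.maximum(treated, control)
        else:
            stat = np.minimum(treated, control)
        keep &= stat > criteria.intensity_floor_log2
    retained = [m for m in norm.mirna_ids if keep[m]]
    logger.info("expression filter retained %d of %d miRNAs", len(retained), len(keep))
    return retained


def fold_changes(norm: NormalizedMatrix, line: str) -> list[FoldChangeRecord]:
    """Treated/control fold change per miRNA for one line (log2 difference)."""
    treated, control = _condition_means(norm, line)
    diff = treated - control
    return [FoldChangeRecord(m, line, float(diff[m])) for m in norm.mirna_ids]


def exclude_negative_responders(
    fc_negative: dict[str, list[FoldChangeRecord]],
    criteria: ScreenCriteria | None = None,
    candidates: list[str] | None = None,
) -> list[str]:
    """Drop miRNAs responding (>1.5-fold either way) in any HER2-negative line.

    Thresholds are strict ("more than"): a fold change of exactly 1.5 is kept.
    """
    criteria = criteria or ScreenCriteria()
    if not fc_negative:
        raise DesignError("no HER2-negative lines configured")
    fc_map: dict[str, dict[str, float]] = {}
    for line, recs in fc_negative.items():
        for rec in recs:
            fc_map.setdefault(rec.mirna_id, {})[line] = rec.fc_linear
    pool = candidates if candidates is not None else list(fc_map)
    survivors = []
    for mirna in pool:
        fcs = fc_map.get(mirna, {})
        if any(fc > criteria.fc_threshold or fc < criteria.down_threshold for fc in fcs.values()):
            continue
        survivors.append(mirna)
    logger.info("negative-line exclusion retained %d of %d miRNAs", len(survivors), len(pool))
    return survivors


def relative_fold_change(
    fc_pos: FoldChangeRecord, fc_negs: list[FoldChangeRecord]
) -> RfcRecord:
    """RFC of one miRNA in one HER2-positive line.

    In log2 space: positive-line fold change minus the arithmetic mean of the
    negative-line fold changes; on the linear scale this is the ratio to the
    geometric mean of the negative-line fold changes.
    """
    if not fc_negs:
        raise DesignError("RFC requires at least one negative-line fold change")
    for rec in (fc_pos, *fc_negs):
        if not np.isfinite(rec.log2_fc):
            raise ConfigError(f"non-finite fold change for {rec.mirna_id} in {rec.cell_line}")
    neg_mean = float(np.mean([r.log2_fc for r in fc_negs]))
    return RfcRecord(fc_pos.mirna_id, fc_pos.cell_line, fc_pos.log2_fc - neg_mean)


def mean_rfc(rfc_values) -> float:
    """Geometric mean of per-positive-line linear RFC values."""
    arr = np.asarray(list(rfc_values), dtype=float)
    if arr.size == 0:
        raise ConfigError("mean_rfc of an empty list")
    if (arr <= 0).any():
        raise ConfigError("mean_rfc requires positive linear RFC values")
    return float(2.0 ** np.mean(np.log2(arr)))


def _ranked(recs: list[RfcRecord]) -> list[RfcRecord]:
    # strongest response first; tie-break on name for determinism
    return sorted(recs, key=lambda r: (-abs(r.log2_rfc), r.mirna_id))


def screen(norm: NormalizedMatrix, criteria: ScreenCriteria | None = None) -> ScreenReport:
    """Run the full four-step screen and assemble the ranked report."""
    criteria = criteria or ScreenCriteria()
    pos_lines = norm.lines(HER2_POSITIVE)
    neg_lines = norm.lines(HER2_NEGATIVE)
    if not pos_lines or not neg_lines:
        raise DesignError("screen needs at least one HER2-positive and one HER2-negative line")

    expressed = filter_expressed(norm, criteria)
    fc_neg = {line: fold_changes(norm, line) for line in neg_lines}
    survivors = exclude_negative_responders(fc_neg, criteria, candidates=expressed)
    survivor_set = set(survivors)

    fc_neg_by_mirna: dict[str, list[FoldChangeRecord]] = {}
    for recs in fc_neg.values():
        for rec in recs:
            fc_neg_by_mirna.setdefault(rec.mirna_id, []).append(rec)

    per_line_up: dict[str, list[RfcRecord]] = {}
    per_line_down: dict[str, list[RfcRecord]] = {}
    rfc_by_mirna: dict[str, list[RfcRecord]] = {}
    for line in pos_lines:
        ups, downs = [], []
        for rec in fold_changes(norm, line):
            if rec.mirna_id not in survivor_set:
                continue
            rfc = relative_fold_change(rec, fc_neg_by_mirna[rec.mirna_id])
            rfc_by_mirna.setdefault(rec.mirna_id, []).append(rfc)
            if rfc.rfc_linear > criteria.fc_threshold:
                ups.append(rfc)
            elif rfc.rfc_linear < criteria.down_threshold:
                downs.append(rfc)
        per_line_up[line] = _ranked(ups)
        per_line_down[line] = _ranked(downs)

    mean_up, mean_down = [], []
    for mirna, recs in rfc_by_mirna.items():
        m = mean_rfc([r.rfc_linear for r in recs])
        rec = RfcRecord(mirna, "mean", float(np.log2(m)))
        if m > criteria.fc_threshold:
            mean_up.append(rec)
        elif m < criteria.down_threshold:
            mean_down.append(rec)

    report = ScreenReport(
        retained_after_expression_filter=expressed,
        retained_after_negative_exclusion=survivors,
        per_line_up=per_line_up,
        per_line_down=per_line_down,
        mean_up=_ranked(mean_up),
        mean_down=_ranked(mean_down),
        criteria=criteria,
    )
    logger.info(
        "screen: %d expressed, %d after negative-line exclusion, %d up / %d down (cross-line)",
        report.n_expressed,
        report.n_after_exclusion,
        len(report.mean_up),
        len(report.mean_down),
    )
    return report


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray  # scipy linkage encoding (children + merge heights)
    leaf_order: list[int]
    labels: list[str]
    metric: str
    input_kind: str


def correlation_distance_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson correlation between columns.

    A zero-variance column has undefined correlation; its distance to every
    other column is set to 1 (and 0 to itself) with a warning.
    """
    values = np.asarray(values, dtype=float)
    m = values.shape[1]
    sd = values.std(axis=0)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        logger.warning("zero-variance columns %s: correlation distance set to 1", degenerate)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr = np.atleast_2d(corr)
    dist = 1.0 - corr
    for i in degenerate:
        dist[i, :] = 1.0
        dist[:, i] = 1.0
    np.fill_diagonal(dist, 0.0)
    # guard tiny negative round-off
    return np.clip(dist, 0.0, None)


def hierarchical_cluster(
    data: NormalizedMatrix | pd.DataFrame, input_kind: str = "expression"
) -> ClusterResult:
    """Average-linkage clustering of sample columns, 1 - Pearson distance."""
    df = data.values if isinstance(data, NormalizedMatrix) else data
    if df.shape[1] < 2:
        raise DesignError("clustering needs at least two columns")
    dist = correlation_distance_matrix(df.to_numpy())
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    return ClusterResult(
        linkage_matrix=Z,
        leaf_order=[int(i) for i in leaves_list(Z)],
        labels=list(df.columns),
        metric="1 - pearson",
        input_kind=input_kind,
    )


def with_criteria(criteria: ScreenCriteria, **kwargs) -> ScreenCriteria:
    """Return a copy of ``criteria`` with the given fields replaced."""
    return replace(criteria, **kwargs)
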