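"""Group comparisons and correlation analyses at the cohort level.

Links regional PET metrics to genotype (GAA repeat length), blood frataxin,
age, and disease duration: two-group percent differences with Welch,
Mann–Whitney or permutation tests, Pearson correlations with
pairwise-complete missing-data handling, and the f_p-normalised uptake
V_T/f_p used to separate delivery effects from binding effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CohortError

__all__ = [
    "SubjectRecord",
    "GroupComparison",
    "CorrelationResult",
    "compare_groups",
    "correlate",
    "vt_over_fp",
    "permutation_pvalue",
    "benjamini_hochberg",
    "records_from_frames",
]

_GROUPS = ("HV", "FA")
_META_VARS = (
    "age",
    "gaa_short_allele",
    "blood_frataxin",
    "disease_duration",
    "f_p",
)


@dataclass
class SubjectRecord:
    """One participant: metadata plus a region → metric → value map."""

    subject_id: str
    group: str
    age: float = np.nan
    gaa_short_allele: float = np.nan
    blood_frataxin: float = np.nan
    disease_duration: float = np.nan
    f_p: float = np.nan
    metrics: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise CohortError(f"group must be one of {_GROUPS}, got '{self.group}'")
        if np.isfinite(self.f_p) and not 0.0 < self.f_p < 1.0:
            raise CohortError("f_p must lie in (0, 1)")

    def get(self, region: str, metric: str) -> float:
        return self.metrics.get(region, {}).get(metric, np.nan)

    def variable(self, name: str) -> float:
        """Resolve a metadata name or a 'region:metric' spec to a value."""
        if name in _META_VARS:
            return getattr(self, name)
        if ":" in name:
            region, metric = name.split(":", 1)
            return self.get(region, metric)
        raise CohortError(f"unknown variable '{name}'")


@dataclass(frozen=True)
class GroupComparison:
    region: str
    metric: str
    mean_hv: float
    mean_fa: float
    percent_difference: float  # 100·(mean_FA − mean_HV)/mean_HV
    statistic: float
    p_value: float
    test: str
    n_hv: int
    n_fa: int


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    r: float
    p_value: float
    n: int
    flagged: bool = False


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Two-sided permutation p-value for the difference of group means.

    Vectorised label shuffling; includes the observed split, so the p-value
    is never exactly zero.  Serves as the model-free oracle against which
    the parametric tests are validated.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pooled = np.concatenate([x, y])
    n_x = x.size
    observed = abs(x.mean() - y.mean())
    idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    perms = pooled[idx]
    diffs = np.abs(perms[:, :n_x].mean(axis=1) - perms[:, n_x:].mean(axis=1))
    return float((np.sum(diffs >= observed - 1e-12) + 1) / (n_perm + 1))


def compare_groups(
    records: Sequence[SubjectRecord],
    region: str,
    metric: str,
    test: str = "welch",
    n_perm: int = 10_000,
    seed: int = 0,
) -> GroupComparison:
    """Two-group comparison of one regional metric.

    Percent difference is 100·(mean_FA − mean_HV)/mean_HV.  Default test is
    Welch's two-sided t-test; 'mannwhitney' and 'permutation' are available.
    Missing values are dropped listwise per comparison; each group must
    retain at least 3 values.  No multiple-testing correction is applied
    here (comparisons are reported per region); see
    :func:`benjamini_hochberg` for optional FDR control across a family.
    """
    vals = {g: [] for g in _GROUPS}
    for rec in records:
        v = rec.get(region, metric)
        if np.isfinite(v):
            vals[rec.group].append(v)
    hv = np.asarray(vals["HV"], float)
    fa = np.asarray(vals["FA"], float)
    if hv.size < 3 or fa.size < 3:
        raise CohortError(
            f"need >= 3 subjects per group with {region}:{metric}; "
            f"got HV={hv.size}, FA={fa.size}"
        )
    mean_hv, mean_fa = float(hv.mean()), float(fa.mean())
    pct = 100.0 * (mean_fa - mean_hv) / mean_hv if mean_hv != 0 else np.nan
    if test == "welch":
        res = stats.ttest_ind(fa, hv, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(fa, hv, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "permutation":
        statistic = mean_fa - mean_hv
        p = permutation_pvalue(fa, hv, n_perm=n_perm, seed=seed)
    else:
        raise ValueError("test must be 'welch', 'mannwhitney' or 'permutation'")
    return GroupComparison(
        region=region,
        metric=metric,
        mean_hv=mean_hv,
        mean_fa=mean_fa,
        percent_difference=pct,
        statistic=statistic,
        p_value=p,
        test=test,
        n_hv=hv.size,
        n_fa=fa.size,
    )


def correlate(
    records: Sequence[SubjectRecord],
    var_x: str,
    var_y: str,
    group: str | None = "FA",
) -> CorrelationResult:
    """Pearson correlation between two subject-level variables.

    Variables are metadata names (age, gaa_short_allele, blood_frataxin,
    disease_duration, f_p) or 'region:metric' specs.  Pairwise-complete:
    subjects missing either value are dropped.  ``group`` restricts the
    analysis (clinical correlations are within the FA group); pass None to
    pool.  Zero variance in either variable flags the result as undefined.
    """
    xs, ys = [], []
    for rec in records:
        if group is not None and rec.group != group:
            continue
        x, y = rec.variable(var_x), rec.variable(var_y)
        if np.isfinite(x) and np.isfinite(y):
            xs.append(x)
            ys.append(y)
    if len(xs) < 3:
        raise CohortError(f"need >= 3 complete pairs for {var_x} vs {var_y}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(var_x, var_y, np.nan, np.nan, x.size, flagged=True)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(var_x, var_y, float(r), float(p), x.size)


def vt_over_fp(record: SubjectRecord, region: str, metric: str = "VT") -> float:
    """Free-fraction-normalised uptake V_T/f_p for one region.

    Dividing by f_p removes plasma-protein-binding differences between
    groups; a group effect present in V_T but absent in V_T/f_p indicates
    the apparent difference is driven by f_p, not by tissue binding.
    """
    if not np.isfinite(record.f_p) or record.f_p <= 0:
        raise CohortError(f"subject {record.subject_id} has no usable f_p")
    vt = record.get(region, metric)
    if not np.isfinite(vt):
        raise CohortError(f"subject {record.subject_id} lacks {region}:{metric}")
    return vt / record.f_p


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional FDR control)."""
    p = np.asarray(p_values, float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out


def records_from_frames(
    subjects: pd.DataFrame, metrics: pd.DataFrame
) -> list[SubjectRecord]:
    """Assemble SubjectRecords from a subject table and a long metric table.

    ``metrics`` needs columns subject_id, region, metric, value; ``subjects``
    needs subject_id and group, with the standard metadata columns optional.
    """
    meta_cols = [c for c in _META_VARS if c in subjects.columns]
    by_subject: dict[str, dict[str, dict[str, float]]] = {}
    for row in metrics.itertuples():
        by_subject.setdefault(str(row.subject_id), {}).setdefault(
            str(row.region), {}
        )[str(row.metric)] = float(row.value)
    records = []
    for row in subjects.itertuples():
        kwargs = {c: float(getattr(row, c)) for c in meta_cols}
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                metrics=by_subject.get(str(row.subject_id), {}),
                **kwargs,
            )
        )
    return records
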