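"""Genomic statistics: proximity score, peak-to-trough ratio, and their link.

The proximity score (PS) summarizes how tightly the genes of functional
modules (e.g. metabolic pathway modules) are packed on a genome: pool the
pairwise distances between genes of the same module across all modules,
take the first quartile Q1, and report ``PS = -log2(Q1)``. Larger PS means
tighter clustering.

The peak-to-trough ratio (PTR) is the sequencing-coverage ratio between
windows centered on the replication origin and terminus; under the
Helmstetter–Cooper model ``log2 PTR = C / tau``, so it proxies replication
activity and hence the shortest division times a species attains.

Species whose mean log2 PTR significantly exceeds 1 (PTR > 2) carry nested
replication forks (mero-oligoploidy). The association layer regresses PS
on log2 PTR summaries and compares PS between mero-oligoploid and other
species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenomeAnnotation",
    "CoverageProfile",
    "proximity_score",
    "module_pair_distances",
    "ptr_from_coverage",
    "ptr_tests",
    "PtrTestResult",
    "ps_ptr_association",
    "AssociationResult",
]


@dataclass
class GenomeAnnotation:
    """Gene coordinates plus functional-module membership.

    genes: list of (gene_id, start, end, strand) with 0-based half-open
    coordinates; modules: mapping module_id -> iterable of gene ids.
    Modules with fewer than two genes contribute no distances.
    """

    genome_length: int
    genes: list[tuple[str, int, int, str]]
    modules: dict[str, set] = field(default_factory=dict)
    circular: bool = True

    def __post_init__(self) -> None:
        ids = set()
        for gid, start, end, _strand in self.genes:
            if not (0 <= start < end <= self.genome_length):
                raise ValueError(f"gene {gid!r} outside genome: [{start}, {end})")
            ids.add(gid)
        for mod, members in self.modules.items():
            unknown = set(members) - ids
            if unknown:
                raise ValueError(f"module {mod!r} references unknown genes {unknown}")
            self.modules[mod] = set(members)

    def midpoints(self) -> dict[str, float]:
        return {gid: (start + end) / 2.0 for gid, start, end, _ in self.genes}


@dataclass
class CoverageProfile:
    """Per-position read depth in two windows centered on ori and ter."""

    ori_positions: np.ndarray
    ori_depth: np.ndarray
    ter_positions: np.ndarray
    ter_depth: np.ndarray
    genome_length: int = 0

    def __post_init__(self) -> None:
        for name in ("ori_positions", "ori_depth", "ter_positions", "ter_depth"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.ori_depth < 0) or np.any(self.ter_depth < 0):
            raise ValueError("coverage depth must be non-negative")


def _circular_distance(a: float, b: float, genome_length: int, circular: bool) -> float:
    d = abs(a - b)
    if circular:
        d = min(d, genome_length - d)
    return d


def module_pair_distances(ann: GenomeAnnotation) -> np.ndarray:
    """All unordered within-module gene-pair distances, pooled over modules.

    Distances are measured between gene midpoints, as the minimum distance
    around the (circular) chromosome, in nucleotides.
    """
    mid = ann.midpoints()
    dists: list[float] = []
    for members in ann.modules.values():
        ms = sorted(members)
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                dists.append(
                    _circular_distance(
                        mid[ms[i]], mid[ms[j]], ann.genome_length, ann.circular
                    )
                )
    return np.asarray(dists, dtype=float)


def proximity_score(ann: GenomeAnnotation) -> float:
    """PS = -log2(Q1) of pooled within-module gene-pair distances.

    Q1 is the first quartile (linear-interpolation quantile) of the pooled
    distance list. Raises if no module has two or more genes or if Q1 is
    not positive (coincident gene midpoints).
    """
    dists = module_pair_distances(ann)
    if dists.size == 0:
        raise ValueError("proximity score undefined: no module with >= 2 genes")
    q1 = float(np.quantile(dists, 0.25))
    if q1 <= 0:
        raise ValueError("proximity score undefined: first-quartile distance is 0")
    return -float(np.log2(q1))


def ptr_from_coverage(cov: CoverageProfile) -> float:
    """log2 of mean ori-window depth over mean ter-window depth."""
    ori_mean = float(np.mean(cov.ori_depth))
    ter_mean = float(np.mean(cov.ter_depth))
    if ter_mean <= 0 or ori_mean <= 0:
        raise ValueError("both windows need positive mean depth")
    return float(np.log2(ori_mean / ter_mean))


@dataclass(frozen=True)
class PtrTestResult:
    """Per-species location tests on replicate log2 PTR values."""

    n: int
    mean: float
    ci95: tuple[float, float]
    p_gt0: float
    p_gt1: float
    mero_oligoploid: bool
    excluded: bool = False
    reason: str = ""


def ptr_tests(log2ptrs, min_libraries: int = 5, alpha: float = 0.01) -> PtrTestResult:
    """One-sided t-tests of mean log2 PTR > 0 (PTR > 1) and > 1 (PTR > 2).

    Species with fewer than ``min_libraries`` replicate libraries are
    excluded (returned with ``excluded=True``). A species is flagged
    mero-oligoploid when the >1 test reaches p <= alpha (default 0.01).
    Also reports the mean with its 95% confidence interval.
    """
    values = np.asarray(log2ptrs, dtype=float)
    n = values.size
    if n < min_libraries:
        return PtrTestResult(
            n=n,
            mean=float(values.mean()) if n else float("nan"),
            ci95=(float("nan"), float("nan")),
            p_gt0=float("nan"),
            p_gt1=float("nan"),
            mero_oligoploid=False,
            excluded=True,
            reason=f"only {n} libraries (minimum {min_libraries})",
        )
    mean = float(values.mean())
    sem = stats.sem(values)
    if sem == 0:
        # Degenerate replicates: the test statistic is +/- infinity.
        p0 = 0.0 if mean > 0 else 1.0
        p1 = 0.0 if mean > 1 else 1.0
        ci = (mean, mean)
    else:
        p0 = float(stats.ttest_1samp(values, 0.0, alternative="greater").pvalue)
        p1 = float(stats.ttest_1samp(values, 1.0, alternative="greater").pvalue)
        lo, hi = stats.t.interval(0.95, n - 1, loc=mean, scale=sem)
        ci = (float(lo), float(hi))
    return PtrTestResult(
        n=n,
        mean=mean,
        ci95=ci,
        p_gt0=p0,
        p_gt1=p1,
        mero_oligoploid=bool(p1 <= alpha),
    )


@dataclass
class AssociationResult:
    """OLS of log2 PTR on PS, plus a PS group comparison.

    Wraps the underlying statsmodels results object (``ols_results``).
    """

    slope: float
    intercept: float
    slope_pvalue: float
    adj_r_squared: float
    n: int
    level: str
    group_test_pvalue: float | None
    ols_results: object

    def summary(self) -> str:
        lines = [
            f"PS ~ log2PTR association ({self.level} level, n={self.n})",
            f"  slope      {self.slope: .4f}  (p = {self.slope_pvalue:.3g})",
            f"  intercept  {self.intercept: .4f}",
            f"  adj. R^2   {self.adj_r_squared: .4f}",
        ]
        if self.group_test_pvalue is not None:
            lines.append(
                f"  PS mero-oligoploid vs other (one-sided t): p = {self.group_test_pvalue:.3g}"
            )
        return "\n".join(lines)


def ps_ptr_association(
    table: pd.DataFrame,
    level: str = "species",
    group_col: str | None = None,
) -> AssociationResult:
    """Regress mean log2 PTR on the proximity score across species.

    ``table`` needs columns ``species``, ``ps`` and ``log2ptr`` (one row per
    species), optionally ``genus`` (for ``level='genus'``, values are first
    averaged within genus) and a boolean group column (e.g. the
    mero-oligoploid flag) for the two-group PS comparison, which tests
    one-sided that the flagged group has larger PS.
    """
    import statsmodels.api as sm

    df = table.copy()
    required = {"ps", "log2ptr"}
    if not required <= set(df.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if level == "genus":
        if "genus" not in df.columns:
            raise ValueError("genus-level association needs a 'genus' column")
        df = df.groupby("genus", as_index=False)[["ps", "log2ptr"]].mean()
    if len(df) < 3:
        raise ValueError("association needs at least 3 rows")
    if float(np.var(df["ps"])) == 0:
        raise ValueError("degenerate predictor: PS has zero variance")
    X = sm.add_constant(df["ps"].to_numpy())
    fit = sm.OLS(df["log2ptr"].to_numpy(), X).fit()

    group_p = None
    if group_col is not None:
        if group_col not in table.columns:
            raise ValueError(f"missing group column {group_col!r}")
        flagged = table.loc[table[group_col].astype(bool), "ps"].to_numpy()
        other = table.loc[~table[group_col].astype(bool), "ps"].to_numpy()
        if flagged.size >= 2 and other.size >= 2:
            group_p = float(
                stats.ttest_ind(flagged, other, alternative="greater").pvalue
            )
    return AssociationResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_pvalue=float(fit.pvalues[1]),
        adj_r_squared=float(fit.rsquared_adj),
        n=len(df),
        level=level,
        group_test_pvalue=group_p,
        ols_results=fit,
    )
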