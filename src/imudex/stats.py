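"""Dexterity assessment: standardization, Ward clustering and
Kruskal-Wallis validation.

Subjects are clustered on standardized features (z-scores, so Euclidean
distance between rows is the standardized Euclidean distance) with Ward's
minimum-variance linkage, cut into k groups. Group differences per
variable are then validated with the tie-corrected Kruskal-Wallis rank
test (a nonparametric one-way ANOVA, appropriate for small heterogeneous
samples), with Bonferroni adjustment across variables reported alongside.

The module exposes both plain functions and a small model object,
:class:`DexterityAssessment`, whose :meth:`~DexterityAssessment.fit`
returns a results object with the group labels, per-group summaries, the
test table and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

from .io import ValidationError


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero, the convention of printed tables
    (banker's rounding would turn 22.675 into 22.67).

    Representation noise below 1e-10 is stripped first so a value that
    is 22.675 in exact decimal arithmetic rounds up even when the
    nearest double sits fractionally below it.
    """
    q = Decimal(1).scaleb(-decimals)
    clean = Decimal(repr(round(float(x), 10)))
    return float(clean.quantize(q, rounding=ROUND_HALF_UP))


def t_ratio(t_span: float, total_task1: float) -> float:
    """Efficiency indicator T_Span / Total_Task1 (>= 1; lower is better).

    Total_Task1 is the time spent actually transporting pieces, so the
    ratio measures how much of the exercise was overhead (errors,
    hesitation, unnecessary movements).
    """
    if total_task1 <= 0:
        raise ValidationError("total_task1 must be positive")
    return t_span / total_task1


def standardize(features: pd.DataFrame | np.ndarray):
    """Per-variable z-scores with the sample (n-1) standard deviation."""
    arr = np.asarray(features, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with >= 2 subjects")
    sd = arr.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = (list(np.asarray(features.columns)[zero])
                 if isinstance(features, pd.DataFrame) else zero.tolist())
        raise ValidationError(f"zero-variance variable(s): {names}")
    z = (arr - arr.mean(axis=0)) / sd
    if isinstance(features, pd.DataFrame):
        return pd.DataFrame(z, index=features.index,
                            columns=features.columns)
    return z


def ward_cluster(features: pd.DataFrame | np.ndarray,
                 k: int) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative Ward clustering cut at k clusters.

    Expects standardized features; each merge minimizes the increase in
    total within-cluster sum of squares (Ward.D2 on Euclidean
    distances). Returns (labels in 1..k, SciPy linkage matrix).
    """
    arr = np.asarray(features, dtype=float)
    n = arr.shape[0]
    if not 2 <= k <= n:
        raise ValidationError(f"k must be in [2, {n}]")
    tree = linkage(arr, method="ward")
    labels = fcluster(tree, k, criterion="maxclust")
    return labels, tree


def group_summary(records: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-group mean and sample sd of every variable.

    ``groups`` assigns one label per row of ``records``. Singleton groups
    get sd = 0 and are marked by their n. Values are returned unrounded;
    use :func:`round_half_away` for table reproduction.
    """
    groups = pd.Series(np.asarray(groups), index=records.index,
                       name="group")
    if groups.isna().any():
        raise ValidationError("every record must be assigned to a group")
    rows = []
    for label, sub in records.groupby(groups, sort=True):
        if sub.empty:
            raise ValidationError(f"empty group {label!r}")
        row = {"group": label, "n": len(sub)}
        for col in records.columns:
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sd"] = (float(sub[col].std(ddof=1))
                                if len(sub) > 1 else 0.0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


@dataclass
class KWResult:
    """Kruskal-Wallis outcome for one variable."""

    variable: str
    H: float
    p: float
    p_bonferroni: float
    df: int
    degenerate: bool = False


def kruskal_wallis(values, groups, m: int = 1,
                   variable: str = "") -> KWResult:
    """Tie-corrected Kruskal-Wallis rank test across groups.

    H is the rank statistic divided by the tie-correction factor
    1 - sum(t^3 - t)/(N^3 - N); p is the upper tail of chi-square with
    k - 1 degrees of freedom, and ``p_bonferroni = min(1, m * p)`` adjusts
    for ``m`` simultaneous comparisons. All-identical values are a
    degenerate case reported as H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValidationError("need >= 2 nonempty groups")
    if values.size < 3:
        raise ValidationError("need at least 3 observations in total")
    if np.all(values == values[0]):
        return KWResult(variable, 0.0, 1.0, 1.0, len(samples) - 1,
                        degenerate=True)
    H, p = sps.kruskal(*samples)
    return KWResult(variable, float(H), float(p), min(1.0, m * float(p)),
                    len(samples) - 1)


def classify_dexterity(metrics: pd.DataFrame,
                       return_tree: bool = False,
                       silhouette_threshold: float = 0.3):
    """Split subjects into dexterity Type 1 / Type 2 by Ward clustering.

    ``metrics`` has one row per subject and the metric variables as
    columns (Duration, Movements, Disp, Disp_theta for the pegboard
    exercise). Features are standardized, clustered with Ward linkage and
    cut at k = 2; the cluster with the lower mean Duration (first column
    if no column named like duration) is labelled "Type 1" — the
    higher-dexterity group. A split whose mean silhouette falls below
    ``silhouette_threshold`` is reported but flagged unstable (a
    homogeneous cohort split at random lands near 0.25; genuinely
    separated groups sit well above 0.35).

    Returns a pandas Series of labels (plus the linkage tree and the
    stability flag when ``return_tree`` is set).
    """
    z = standardize(metrics)
    labels, tree = ward_cluster(z, 2)
    dur_col = next((c for c in metrics.columns
                    if str(c).lower().startswith("dur")),
                   metrics.columns[0])
    means = {lab: metrics.loc[labels == lab, dur_col].mean()
             for lab in (1, 2)}
    type1 = min(means, key=means.get)
    named = pd.Series(np.where(labels == type1, "Type 1", "Type 2"),
                      index=metrics.index, name="dexterity")
    stable = _mean_silhouette(np.asarray(z, float),
                              labels) >= silhouette_threshold
    if return_tree:
        return named, tree, stable
    return named


def _mean_silhouette(z: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width over subjects (Euclidean, two clusters)."""
    from scipy.spatial.distance import cdist
    d = cdist(z, z)
    svals = []
    for i in range(len(z)):
        same = (labels == labels[i])
        same[i] = False
        if not same.any():
            svals.append(0.0)
            continue
        a = d[i, same].mean()
        b = d[i, ~same & (labels != labels[i])].mean()
        svals.append((b - a) / max(a, b))
    return float(np.mean(svals))


class DexterityAssessment:
    """Clustering + rank-test assessment of a subjects x variables table.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per subject, one column per metric variable.
    k : int
        Number of groups to cut the Ward tree into.

    Examples
    --------
    >>> model = DexterityAssessment(table, k=2)
    >>> res = model.fit()
    >>> res.labels; res.group_summary; res.kw_table; print(res.summary())
    """

    def __init__(self, data: pd.DataFrame, k: int = 2):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(data)
        self.data = data
        self.k = k

    @classmethod
    def from_metrics(cls, records, exercise: int = 3, sensor: int = 1,
                     k: int = 2) -> "DexterityAssessment":
        """Build from a long metrics table (one row per
        subject/exercise/sensor) by selecting one exercise and sensor."""
        df = pd.DataFrame(records)
        # accept both the in-memory and the metrics-CSV column dialects
        df = df.rename(columns={"duration_s": "duration",
                                "disp_m": "disp",
                                "disptheta_deg": "disp_theta"})
        sel = df[(df["exercise"] == exercise) & (df["sensor"] == sensor)]
        wide = sel.set_index("subject")[
            ["duration", "movements", "disp", "disp_theta"]]
        return cls(wide, k=k)

    def fit(self, bonferroni_m: int | None = None) -> "DexterityResults":
        z = standardize(self.data)
        labels, tree = ward_cluster(z, self.k)
        if self.k == 2:
            named = classify_dexterity(self.data)
        else:
            named = pd.Series([f"Group {int(l)}" for l in labels],
                              index=self.data.index, name="group")
        m = bonferroni_m if bonferroni_m is not None \
            else self.data.shape[1]
        kw_rows = [kruskal_wallis(self.data[c].to_numpy(), named.to_numpy(),
                                  m=m, variable=str(c))
                   for c in self.data.columns]
        return DexterityResults(self, named, tree,
                                group_summary(self.data, named), kw_rows)


class DexterityResults:
    """Fitted dexterity assessment: labels, summaries and tests."""

    def __init__(self, model, labels, tree, summary_table, kw_results):
        self.model = model
        self.labels = labels
        self.tree = tree
        self.group_summary = summary_table
        self.kw_results = kw_results

    @property
    def kw_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "variable": r.variable, "H": r.H, "p": r.p,
            "p_bonferroni": r.p_bonferroni, "df": r.df,
        } for r in self.kw_results]).set_index("variable")

    def summary(self) -> str:
        lines = [f"Dexterity assessment: {len(self.labels)} subjects, "
                 f"k={self.model.k}", ""]
        for grp, sub in self.labels.groupby(self.labels):
            lines.append(f"{grp}: {{{', '.join(map(str, sub.index))}}}")
        lines += ["", "Group summary (mean (sd)):"]
        for grp, row in self.group_summary.iterrows():
            cells = [f"{c}={row[f'{c}_mean']:.2f} ({row[f'{c}_sd']:.2f})"
                     for c in self.model.data.columns]
            lines.append(f"  {grp} (n={int(row['n'])}): " + ", ".join(cells))
        lines += ["", "Kruskal-Wallis (tie-corrected, chi-square "
                  "approximation):"]
        for r in self.kw_results:
            flag = "  [degenerate]" if r.degenerate else ""
            lines.append(f"  {r.variable}: H={r.H:.4f}, p={r.p:.4f}, "
                         f"Bonferroni p={r.p_bonferroni:.4f}{flag}")
        return "\n".join(lines)
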