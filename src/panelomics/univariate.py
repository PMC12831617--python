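"""Per-feature two-group statistics and cohort-characteristics tests.

Implements the univariate screening stage of the pipeline: classical
pooled-variance Student's t per feature, the single-feature ROC AUC
(Mann-Whitney statistic scaled to [0, 1]), per-layer counting of
features with p <= alpha, top-K selection per omics layer, and the
two-sided Fisher exact test for 2x2 cohort-characteristic tables.

Raw (unadjusted) p-values are thresholded throughout: the screening
stage of this workflow reports counts at p <= 0.05 without multiplicity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, PanelomicsError
from .tables import LAYERS, FeatureRanking, OmicsTable, PhenotypeLabels


@dataclass
class TTestResult:
    """Pooled-variance two-sided t-test for one feature."""

    feature_id: str
    t: float
    p: float
    df: int
    degenerate: bool = False


@dataclass
class UnivariateAUC:
    """Single-feature ROC AUC, raw orientation (not folded above 0.5).

    ``direction`` is +1 when cases tend to exceed controls, -1 when
    controls exceed cases, 0 at exactly 0.5.
    """

    feature_id: str
    auc: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.auc - 0.5))


def _split_groups(values, labels: PhenotypeLabels):
    values = np.asarray(values, dtype=float)
    y = labels.label
    keep = ~np.isnan(values)
    return values[keep & (y == 1)], values[keep & (y == 0)]


def student_t(values, labels: PhenotypeLabels, feature_id: str = "") -> TTestResult:
    """Classical (pooled-variance) two-sided Student t-test, cases vs controls.

    Missing values are dropped per feature.  With zero pooled variance
    the result is degenerate: p = 1 if the group means are equal, else
    p = 0.
    """
    cases, controls = _split_groups(values, labels)
    if len(cases) < 2 or len(controls) < 2:
        raise InsufficientDataError(
            f"need >=2 samples per class, got {len(cases)}/{len(controls)}"
        )
    n1, n2 = len(cases), len(controls)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * cases.var(ddof=1) + (n2 - 1) * controls.var(ddof=1)) / df
    if s2 == 0:
        equal = cases.mean() == controls.mean()
        return TTestResult(
            feature_id,
            t=0.0 if equal else np.inf * np.sign(cases.mean() - controls.mean()),
            p=1.0 if equal else 0.0,
            df=df,
            degenerate=True,
        )
    res = stats.ttest_ind(cases, controls, equal_var=True)
    return TTestResult(feature_id, t=float(res.statistic), p=float(res.pvalue), df=df)


def feature_auc(values, labels: PhenotypeLabels, feature_id: str = "") -> UnivariateAUC:
    """ROC AUC of one feature used directly as a score.

    Computed as the Mann-Whitney U statistic divided by n1*n2, with
    tied case/control pairs counted 1/2.  Orientation is kept raw: an
    AUC below 0.5 means the feature is lower in cases.
    """
    cases, controls = _split_groups(values, labels)
    if len(cases) == 0 or len(controls) == 0:
        raise InsufficientDataError("both classes must be present")
    # U = #(case > control) + 0.5 * #(case == control) over all pairs
    u = stats.mannwhitneyu(cases, controls, alternative="two-sided").statistic
    return UnivariateAUC(feature_id, auc=float(u / (len(cases) * len(controls))))


def univariate_table(table: OmicsTable, labels: PhenotypeLabels):
    """Per-feature t, p, df and AUC for every feature; returns a DataFrame."""
    import pandas as pd

    labels = labels.aligned_to(table)
    rows = []
    for f in table.feature_ids:
        v = table.data[f].to_numpy()
        tr = student_t(v, labels, f)
        au = feature_auc(v, labels, f)
        rows.append(
            {
                "feature_id": f,
                "layer": table.layer_of(f),
                "t": tr.t,
                "p": tr.p,
                "df": tr.df,
                "auc": au.auc,
            }
        )
    return pd.DataFrame(rows)


def significant_count(
    table: OmicsTable, labels: PhenotypeLabels, alpha: float = 0.05
) -> dict[str, int]:
    """Number of features per layer with raw t-test p <= alpha."""
    stats_df = univariate_table(table, labels)
    counts = {layer: 0 for layer in LAYERS if table.layer_features(layer)}
    hit = stats_df[stats_df["p"] <= alpha]
    for layer in counts:
        counts[layer] = int((hit["layer"] == layer).sum())
    return counts


def top_k_per_omics(
    table: OmicsTable, labels: PhenotypeLabels, k: int
) -> dict[str, FeatureRanking]:
    """Per-layer ranking by ascending p (ties: |t| descending, then id)."""
    stats_df = univariate_table(table, labels)
    out = {}
    for layer in LAYERS:
        feats = table.layer_features(layer)
        if not feats:
            continue
        if k > len(feats):
            raise ValueError(f"k={k} exceeds {layer} layer size {len(feats)}")
        sub = stats_df[stats_df["layer"] == layer].copy()
        sub["abs_t"] = sub["t"].abs()
        sub = sub.sort_values(
            ["p", "abs_t", "feature_id"], ascending=[True, False, True]
        )
        ordered = sub["feature_id"].tolist()
        # score = -p so that the reported scores are non-increasing
        out[layer] = FeatureRanking(
            method=f"t_test[{layer}]",
            ordered_features=ordered,
            scores=-sub["p"].to_numpy(),
            selected=ordered[:k],
            raw_scores=dict(zip(sub["feature_id"], sub["p"])),
        )
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Uses the point-probability rule: p is the sum of hypergeometric
    probabilities of every table with the observed margins whose point
    probability does not exceed that of the observed table.  Computed
    in exact integer arithmetic, so no floating-point comparison
    tolerance is needed.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise PanelomicsError("table must be 2x2")
    a, b, c, d = int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    if min(a, b, c, d) < 0:
        raise PanelomicsError("counts must be nonnegative")
    n = a + b + c + d
    if n < 1:
        raise PanelomicsError("grand total must be >= 1")
    r1, r2, c1 = a + b, c + d, a + c
    # weight(k) = C(r1, k) * C(r2, c1-k); p(k) = weight(k) / C(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = comb(r1, a) * comb(r2, c1 - a)
    total = comb(n, c1)
    tail = sum(
        w
        for k in range(lo, hi + 1)
        if (w := comb(r1, k) * comb(r2, c1 - k)) <= obs
    )
    return tail / total
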