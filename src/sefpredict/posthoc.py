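"""Channel-level biomarker statistics on the model's top features.

After the elastic-net protocol, the most predictive features are examined
outside the model: Pearson correlation of each top spectral-event feature
with HAM-D %change (Bonferroni-corrected across the tested features),
responder/non-responder and remitter/non-remitter t-tests, and an
age-matched patient-control comparison.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PosthocResult:
    feature: str
    pearson_r: float
    p_raw: float
    p_corrected: float
    m_tests: int
    method: str = "bonferroni"

    def __post_init__(self) -> None:
        assert np.isnan(self.p_corrected) or self.p_corrected >= self.p_raw - 1e-15


@dataclass
class MatchedSample:
    mdd_ids: list
    hc_ids: list
    age_differences: list[float]

    @property
    def mean_abs_age_difference(self) -> float:
        return float(np.mean(np.abs(self.age_differences)))


def top_k_features(importances: pd.DataFrame, k: int = 5) -> list[str]:
    """The k features of largest absolute permutation importance;
    ties resolve alphabetically."""
    if len(importances) < k:
        raise ValueError(f"need at least k={k} features")
    ranked = importances.assign(_a=importances["importance"].abs()).sort_values(
        ["_a", "feature"], ascending=[False, True], kind="mergesort"
    )
    return list(ranked["feature"].head(k))


def feature_outcome_correlation(
    values: np.ndarray, pct_change: np.ndarray, m_tests: int = 4,
    feature: str = "", method: str = "bonferroni",
) -> PosthocResult:
    """Pearson correlation of a baseline feature with HAM-D %change,
    with Bonferroni (default) or Holm-ready correction: p_corr = min(1, m*p)."""
    values = np.asarray(values, dtype=float)
    pct_change = np.asarray(pct_change, dtype=float)
    ok = np.isfinite(values) & np.isfinite(pct_change)
    if ok.sum() < 3:
        raise ValueError("need >= 3 finite pairs")
    v, y = values[ok], pct_change[ok]
    if v.std() == 0 or y.std() == 0:
        return PosthocResult(feature, np.nan, np.nan, np.nan, m_tests, method)
    r, p = stats.pearsonr(v, y)
    return PosthocResult(feature, float(r), float(p), min(1.0, m_tests * float(p)),
                         m_tests, method)


def correct_pvalues(p_raw: list[float], method: str = "bonferroni") -> list[float]:
    """Bonferroni (default) or Holm step-down correction."""
    p = np.asarray(p_raw, dtype=float)
    m = p.size
    if method == "bonferroni":
        return list(np.minimum(1.0, m * p))
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(1.0, running)
        return list(adj)
    raise ValueError(f"unknown correction method {method!r}")


def group_ttest(
    values_a: np.ndarray, values_b: np.ndarray, alternative: str = "two-sided",
) -> tuple[float, float]:
    """Student pooled-variance two-sample t-test, group_a minus group_b.

    With responders as group_a, shorter responder durations give a negative
    t.  ``alternative`` in {"two-sided", "less", "greater"} refers to the
    group_a - group_b difference.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate zero variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    return float(t), float(p)


def age_match_subsample(
    mdd_ages: np.ndarray, hc_ages: np.ndarray, seed: int = 0,
    mdd_ids: list | None = None, hc_ids: list | None = None,
) -> MatchedSample:
    """Greedy nearest-age matching of one MDD patient per healthy control,
    without replacement; HCs are processed in seeded random order.  Ties in
    age distance resolve to the earlier MDD index."""
    mdd_ages = np.asarray(mdd_ages, dtype=float)
    hc_ages = np.asarray(hc_ages, dtype=float)
    if len(mdd_ages) < len(hc_ages):
        raise ValueError("need at least as many MDD patients as HCs")
    mdd_ids = list(range(len(mdd_ages))) if mdd_ids is None else list(mdd_ids)
    hc_ids = list(range(len(hc_ages))) if hc_ids is None else list(hc_ids)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(hc_ages))
    available = list(range(len(mdd_ages)))
    picked: dict[int, int] = {}
    for h in order:
        dists = np.abs(mdd_ages[available] - hc_ages[h])
        j = int(np.argmin(dists))  # argmin takes the earliest on ties
        picked[int(h)] = available.pop(j)
    sel = [picked[h] for h in range(len(hc_ages))]
    diffs = [float(mdd_ages[m] - hc_ages[h]) for h, m in enumerate(sel)]
    return MatchedSample(
        mdd_ids=[mdd_ids[m] for m in sel], hc_ids=hc_ids,
        age_differences=diffs,
    )


def plot_feature_outcome(
    values: np.ndarray, clinical: pd.DataFrame, feature: str, path,
) -> None:
    """Optional figure: outcome scatter (left) and responder strip plot
    (right) for one channel-level feature; saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    pct = clinical["pct_change"].to_numpy()
    resp = clinical["responder"].to_numpy().astype(bool)

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
    ax1.scatter(values, pct, s=18, alpha=0.7)
    ax1.set_xlabel(feature)
    ax1.set_ylabel("HAM-D %change")
    rng = np.random.default_rng(0)  # fixed display jitter
    for i, (flag, label) in enumerate([(~resp, "non-responder"), (resp, "responder")]):
        x = i + 0.08 * rng.standard_normal(flag.sum())
        ax2.plot(x, values[flag], "o", ms=4, alpha=0.6)
        ax2.hlines(np.nanmean(values[flag]), i - 0.2, i + 0.2, color="k")
    ax2.set_xticks([0, 1], ["non-resp.", "resp."])
    ax2.set_ylabel(feature)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def posthoc_report(
    feature_values: pd.DataFrame, clinical: pd.DataFrame,
    top_features: list[str], sef_top_features: list[str] | None = None,
    method: str = "bonferroni",
) -> dict:
    """Correlations (corrected across the tested SEF features) plus
    responder and remitter contrasts for each significant feature.

    ``feature_values`` is subjects x features (raw scale); ``clinical``
    provides pct_change / responder / remitter aligned by subject_id.
    """
    cl = clinical.set_index("subject_id")
    vals = feature_values.loc[cl.index]
    sef_feats = [f for f in top_features if f in vals.columns
                 and f != "baseline_hamd"] if sef_top_features is None else sef_top_features
    m = len(sef_feats)

    correlations = [
        feature_outcome_correlation(
            vals[f].to_numpy(), cl["pct_change"].to_numpy(), m_tests=m,
            feature=f, method=method,
        )
        for f in sef_feats
    ]
    if method == "holm":
        adj = correct_pvalues([c.p_raw for c in correlations], "holm")
        for c, a in zip(correlations, adj):
            c.p_corrected = a

    contrasts = {}
    for c in correlations:
        if not (np.isfinite(c.p_corrected) and c.p_corrected < 0.05):
            continue
        v = vals[c.feature].to_numpy()
        resp = cl["responder"].to_numpy().astype(bool)
        rem = cl["remitter"].to_numpy().astype(bool)
        # one-sided direction implied by the correlation: improvement means
        # very negative %change, so a positive r(feature, pct_change) puts
        # responders on the low side of the feature and vice versa
        alternative = "less" if c.pearson_r > 0 else "greater"
        entry = {}
        for name, flag in (("responder", resp), ("remitter", rem)):
            a, b = v[flag], v[~flag]
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if len(a) >= 2 and len(b) >= 2:
                t, p = group_ttest(a, b, alternative=alternative)
                entry[name] = {
                    "t": t, "p_one_sided": p, "alternative": alternative,
                    "mean_positive": float(a.mean()), "mean_negative": float(b.mean()),
                    "n_positive": int(len(a)), "n_negative": int(len(b)),
                }
        contrasts[c.feature] = entry

    return {
        "tested_features": sef_feats,
        "m_tests": m,
        "correction": method,
        "correlations": [vars(c) for c in correlations],
        "group_contrasts": contrasts,
    }
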