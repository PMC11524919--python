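"""Model interpretation: SHAP attributions, probability-SRS correlation,
and cohort summary statistics.

For a linear model scored on (assumed independent) features, the
Shapley value of feature j for row i has the exact closed form
``w_j * (x_ij - mean_j)`` with base value equal to the mean decision
value; it is computed directly rather than estimated by sampling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, OlstError
from .screening import FittedSVM, ModelResult


@dataclass
class ShapReport:
    """Per-participant, per-variable attributions in decision-value units."""

    columns: tuple[str, ...]
    values: np.ndarray              # (n, k)
    base_value: float
    decisions: np.ndarray           # (n,)

    @property
    def variable_order(self) -> list[str]:
        """Variables ordered by decreasing mean |attribution|."""
        imp = np.abs(self.values).mean(axis=0)
        return [self.columns[j] for j in np.argsort(-imp)]

    def to_dict(self) -> dict:
        return {"columns": list(self.columns),
                "values": self.values.tolist(),
                "base_value": self.base_value,
                "variable_order": self.variable_order}


@dataclass
class StatResult:
    statistic: float
    df: float
    p_value: float
    method: str

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df,
                "p_value": self.p_value, "method": self.method}


def linear_shap(model: FittedSVM, X: np.ndarray) -> ShapReport:
    """Exact Shapley attributions of a linear model on the scored data.

    ``base + sum_j attribution_ij`` equals row i's decision value to
    machine precision (additivity identity of Shapley values).
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise OlstError("non-finite feature values")
    Xs = (X - model.mean) / model.scale
    dec = Xs @ model.weights + model.intercept
    center = Xs.mean(axis=0)
    values = model.weights[None, :] * (Xs - center[None, :])
    base = float(center @ model.weights + model.intercept)
    return ShapReport(columns=tuple(model.columns), values=values,
                      base_value=base, decisions=dec)


def spearman_corr(a, b) -> StatResult:
    """Tie-corrected Spearman rank correlation with a t-based p-value.

    p comes from t = r_s * sqrt((n-2)/(1-r_s^2)) on n-2 degrees of
    freedom (the convention behind reporting r_s(n-2)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise OlstError("series lengths differ")
    n = a.size
    if n < 3:
        raise InsufficientDataError("Spearman needs n >= 3")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    sa, sb = ra.std(), rb.std()
    if sa == 0 or sb == 0:
        return StatResult(float("nan"), n - 2, float("nan"),
                          "spearman (undefined: constant input)")
    r = float(np.mean((ra - ra.mean()) * (rb - rb.mean())) / (sa * sb))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return StatResult(r, n - 2, p, "spearman")


def welch_t(a, b) -> StatResult:
    """Welch two-sample t-test with Welch-Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("Welch t needs >= 2 per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        return StatResult(0.0, float(a.size + b.size - 2), 1.0, "welch t")
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return StatResult(float(t), float(df), float(p), "welch t")


def chi2_sex_ratio(table: pd.DataFrame) -> StatResult:
    """Pearson chi-square (df 1, no continuity correction) on the
    2x2 group-by-sex contingency table."""
    ct = pd.crosstab(table["group"], table["sex"])
    if ct.shape != (2, 2):
        counts = ct.to_numpy(dtype=float)
        if (counts.sum(axis=0) == 0).any() or ct.shape[0] < 2:
            return StatResult(float("nan"), 1.0, float("nan"),
                              "chi-square (degenerate table)")
    obs = ct.to_numpy(dtype=float)
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return StatResult(float(chi2), float(df), float(p), "chi-square")


def cohort_stats(table: pd.DataFrame, age: pd.Series | None = None) -> dict:
    """Group descriptive statistics with Welch t (age, SRS) and the sex
    chi-square — the standard participants-characteristics summary."""
    hi = table[table["group"] == "High"]
    lo = table[table["group"] == "Low"]
    if len(hi) == 0 or len(lo) == 0:
        raise InsufficientDataError("both groups must be non-empty")
    out: dict = {
        "n_high": int(len(hi)), "n_low": int(len(lo)),
        "srs": {
            "high_mean": float(hi["srs_total"].mean()),
            "high_sd": float(hi["srs_total"].std(ddof=1)),
            "low_mean": float(lo["srs_total"].mean()),
            "low_sd": float(lo["srs_total"].std(ddof=1)),
            "test": welch_t(hi["srs_total"], lo["srs_total"]).to_dict(),
        },
        "sex_ratio": {
            "high_male": int((hi["sex"] == "male").sum()),
            "high_female": int((hi["sex"] == "female").sum()),
            "low_male": int((lo["sex"] == "male").sum()),
            "low_female": int((lo["sex"] == "female").sum()),
            "test": chi2_sex_ratio(table).to_dict(),
        },
    }
    if age is not None:
        a_hi = age[table["group"] == "High"]
        a_lo = age[table["group"] == "Low"]
        out["age"] = {
            "high_mean": float(a_hi.mean()), "high_sd": float(a_hi.std(ddof=1)),
            "low_mean": float(a_lo.mean()), "low_sd": float(a_lo.std(ddof=1)),
            "test": welch_t(a_hi, a_lo).to_dict(),
        }
    return out


def probability_srs_report(results: dict[str, ModelResult],
                           table: pd.DataFrame) -> dict:
    """Per category: Spearman correlation between the out-of-fold
    High-group probability and the SRS-2 total, scatter data, and the
    SHAP report for the selected model."""
    report: dict = {"categories": {}}
    srs_by_id = dict(zip(table["participant_id"], table["srs_total"]))
    for category, res in results.items():
        srs = np.array([srs_by_id[i] for i in res.ids], dtype=float)
        probs = res.probabilities
        if np.all(probs == probs[0]):
            corr = StatResult(float("nan"), len(probs) - 2, float("nan"),
                              "spearman (undefined: constant probabilities)")
        else:
            corr = spearman_corr(probs, srs)
        cols = list(res.spec.subset)
        sub = table.set_index("participant_id").loc[res.ids, cols]
        shap = linear_shap(res.model, sub.to_numpy(dtype=float))
        report["categories"][category] = {
            "spearman": corr.to_dict(),
            "scatter": [{"id": i, "srs_total": float(s), "probability": float(p)}
                        for i, s, p in zip(res.ids, srs, probs)],
            "shap": shap.to_dict(),
            "selected_variables": cols,
        }
    return report


# -------------------------------------------------------------- plotting

def plot_probability_scatter(report: dict, path) -> None:
    """SRS-total vs High-probability scatter, one panel per category."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    cats = report["categories"]
    fig, axes = plt.subplots(1, len(cats), figsize=(4 * len(cats), 3.5),
                             squeeze=False)
    for ax, (name, c) in zip(axes[0], cats.items()):
        srs = [d["srs_total"] for d in c["scatter"]]
        pr = [d["probability"] for d in c["scatter"]]
        ax.scatter(srs, pr, s=12, alpha=0.7)
        rs = c["spearman"]["statistic"]
        ax.set_title(f"{name} (r_s = {rs:.3f})" if rs == rs else name)
        ax.set_xlabel("SRS-2 total")
        ax.set_ylabel("P(High)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_shap_summary(shap: ShapReport, path) -> None:
    """Strip plot of per-participant attributions, most important on top."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    order = shap.variable_order
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(order) + 1.5))
    rng = np.random.default_rng(0)
    for k, name in enumerate(reversed(order)):
        j = shap.columns.index(name)
        v = shap.values[:, j]
        ax.scatter(v, k + rng.uniform(-0.15, 0.15, size=v.size), s=10, alpha=0.6)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(list(reversed(order)))
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("attribution (decision-value units)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
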