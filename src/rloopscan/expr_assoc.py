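"""Differential expression and covariate association.

Median-of-ratios normalization, a moment-matched negative-binomial Wald
test, Benjamini-Hochberg adjustment, a Mann-Whitney U test with an exact
small-sample mode, gene-class association reports, and the two-species
contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LN2_SQ = math.log(2.0) ** 2
PRIOR_DF = 5.0  # strength of dispersion shrinkage toward the trend


# --------------------------------------------------------------------------
# normalization


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors (genes with any zero count excluded
    from factor estimation). Returns (size_factors, normalized_matrix)."""
    mat = counts.to_numpy(dtype=float)
    if mat.sum() == 0:
        raise ValueError("count matrix is all zero")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has all-positive counts; cannot estimate factors")
    sub = mat[positive]
    log_geo_mean = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geo_mean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    size_factors = pd.Series(factors, index=counts.columns, name="size_factor")
    normalized = counts / factors
    return size_factors, normalized


# --------------------------------------------------------------------------
# multiple testing


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values in the original order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# --------------------------------------------------------------------------
# Mann-Whitney U


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x via mid-rank sums."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[: x.size].sum()
    return r_x - x.size * (x.size + 1) / 2.0


def u_null_counts(n: int, m: int) -> list[int]:
    """Exact null distribution of U (tie-free): counts over u = 0..n*m.

    Coefficients of the Gaussian binomial (n+m choose n)_q, built by
    multiplying (1 - q^(m+i)) and dividing by (1 - q^i) for i = 1..n.
    Exact integer arithmetic, O(n * n*m) additions.
    """
    size = n * m + 1
    arr = [0] * (size + n * 2 + m)  # slack for intermediate degrees
    arr[0] = 1
    for i in range(1, n + 1):
        shift = m + i
        for k in range(len(arr) - 1, shift - 1, -1):
            arr[k] -= arr[k - shift]
        for k in range(i, len(arr)):
            arr[k] += arr[k - i]
    return arr[:size]


def _exact_two_tailed(n: int, m: int, u_obs: float) -> float:
    """Exact two-tailed p: total probability of U at least as far from
    n*m/2 as observed."""
    counts = u_null_counts(n, m)
    total = sum(counts)
    mean_u = n * m / 2.0
    d_obs = abs(u_obs - mean_u)
    extreme = sum(c for u, c in enumerate(counts) if abs(u - mean_u) >= d_obs - 1e-9)
    return extreme / total


def mann_whitney_u(x, y, exact_limit: int = 8) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Exact enumeration when min(n, m) <= ``exact_limit`` and the pooled data
    are tie-free; otherwise a normal approximation with tie and continuity
    corrections. Returns (U for x, two-tailed p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    u = _u_statistic(x, y)

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if min(n, m) <= exact_limit and not has_ties:
        return u, _exact_two_tailed(n, m, u)

    mean_u = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    nm = n + m
    tie_term = np.sum(tie_counts**3 - tie_counts) / (nm * (nm - 1)) if nm > 1 else 0.0
    var_u = n * m / 12.0 * ((nm + 1) - tie_term)
    if var_u <= 0:
        return u, 1.0
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    return u, min(1.0, 2.0 * stats.norm.sf(z))


# --------------------------------------------------------------------------
# differential expression


@dataclass
class DEResult:
    table: pd.DataFrame  # gene_id, base_mean, log2fc, se, p_value, q_value, class
    excluded: list[str]  # all-zero genes

    def classes(self) -> pd.Series:
        return self.table.set_index("gene_id")["class"]


def _pooled_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-gene method-of-moments dispersion shrunk toward the pooled trend."""
    means = []
    var_terms = []
    for idx in groups:
        sub = norm[:, idx]
        means.append(sub.mean(axis=1))
        var_terms.append(sub.var(axis=1, ddof=1))
    mean_all = np.mean(means, axis=0)
    var_all = np.mean(var_terms, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var_all - mean_all) / np.square(mean_all)
    raw = np.clip(np.nan_to_num(raw, nan=0.0), 0.0, 10.0)
    trend = float(np.median(raw[mean_all > 0])) if np.any(mean_all > 0) else 0.1
    n_rep = min(len(idx) for idx in groups)
    weight = (n_rep - 1) / ((n_rep - 1) + PRIOR_DF)  # strong shrinkage at tiny n
    shrunk = weight * raw + (1 - weight) * trend
    return np.maximum(shrunk, 1e-3)


def de_test(
    counts: pd.DataFrame,
    condition_labels: list[str],
    lfc_thresh: float = 1.0,
    q_thresh: float = 0.05,
) -> DEResult:
    """Moment-matched NB Wald test of kd vs control.

    ``condition_labels`` gives 'control'/'kd' per column. log2FC uses a 0.5
    pseudo-count on normalized condition means; the Wald standard error
    comes from the NB variance with a shrunk dispersion.
    """
    labels = np.asarray(condition_labels)
    ctrl_idx = np.flatnonzero(labels == "control")
    kd_idx = np.flatnonzero(labels == "kd")
    if ctrl_idx.size < 2 or kd_idx.size < 2:
        raise ValueError("need >= 2 replicates per condition")

    all_zero = (counts.to_numpy() == 0).all(axis=1)
    excluded = counts.index[all_zero].tolist()
    counts = counts.loc[~all_zero]

    _, norm_df = normalize_counts(counts)
    norm = norm_df.to_numpy(dtype=float)
    phi = _pooled_dispersion(norm, [ctrl_idx, kd_idx])

    mu_c = norm[:, ctrl_idx].mean(axis=1)
    mu_k = norm[:, kd_idx].mean(axis=1)
    log2fc = np.log2(mu_k + 0.5) - np.log2(mu_c + 0.5)

    # delta method: Var(log2 mean) ~ (1/mu + phi) / (n ln^2 2)
    var_c = (1.0 / np.maximum(mu_c, 0.5) + phi) / (ctrl_idx.size * LN2_SQ)
    var_k = (1.0 / np.maximum(mu_k, 0.5) + phi) / (kd_idx.size * LN2_SQ)
    se = np.sqrt(var_c + var_k)
    z = log2fc / se
    # moderated t: residual df plus the prior df contributed by shrinkage;
    # heavier tails than the normal keep 2v2 designs calibrated
    df = (ctrl_idx.size - 1) + (kd_idx.size - 1) + PRIOR_DF
    p = 2.0 * stats.t.sf(np.abs(z), df)
    q = bh_adjust(p)

    table = pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean": (mu_c + mu_k) / 2.0,
            "log2fc": log2fc,
            "se": se,
            "p_value": p,
            "q_value": q,
        }
    ).reset_index(drop=True)
    table["class"] = classify_genes(table, lfc_thresh, q_thresh)
    return DEResult(table=table, excluded=excluded)


def classify_genes(
    de_table: pd.DataFrame, lfc_thresh: float = 1.0, q_thresh: float = 0.05
) -> pd.Series:
    """down / up / nochange partition from log2fc and q-value thresholds."""
    lfc = de_table["log2fc"].to_numpy()
    q = de_table["q_value"].to_numpy()
    cls = np.where(
        (lfc <= -lfc_thresh) & (q <= q_thresh),
        "down",
        np.where((lfc >= lfc_thresh) & (q <= q_thresh), "up", "nochange"),
    )
    return pd.Series(cls, index=de_table.index, name="class")


# --------------------------------------------------------------------------
# association reports


@dataclass
class AssociationReport:
    summary: pd.DataFrame  # per class: n, medians, IQRs for both covariates
    tests: pd.DataFrame  # comparison, covariate, U, p_value, skipped


def _summary_stats(v: np.ndarray) -> dict:
    if v.size == 0:
        return {"median": np.nan, "iqr_lo": np.nan, "iqr_hi": np.nan}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"median": float(med), "iqr_lo": float(q1), "iqr_hi": float(q3)}


def association_report(
    classes: pd.Series,
    gene_lengths: pd.Series,
    motif_counts: pd.Series,
    min_class_n: int = 3,
) -> AssociationReport:
    """Per-class summaries and two-tailed U tests (down vs nochange, up vs
    nochange) on gene length and motif burden."""
    genes = classes.index.intersection(gene_lengths.index).intersection(
        motif_counts.index
    )
    classes = classes.loc[genes]
    covariates = {
        "gene_length": gene_lengths.loc[genes].astype(float),
        "motif_count": motif_counts.loc[genes].astype(float),
    }

    summary_rows = []
    for cls in ("down", "up", "nochange"):
        members = classes[classes == cls].index
        row = {"class": cls, "n": len(members)}
        for name, vals in covariates.items():
            s = _summary_stats(vals.loc[members].to_numpy())
            row.update({f"{name}_{k}": v for k, v in s.items()})
        summary_rows.append(row)

    test_rows = []
    base = classes[classes == "nochange"].index
    for cls in ("down", "up"):
        members = classes[classes == cls].index
        for name, vals in covariates.items():
            if len(members) < min_class_n or len(base) < min_class_n:
                test_rows.append(
                    {
                        "comparison": f"{cls}_vs_nochange",
                        "covariate": name,
                        "U": np.nan,
                        "p_value": np.nan,
                        "skipped": True,
                    }
                )
                continue
            u, p = mann_whitney_u(
                vals.loc[members].to_numpy(), vals.loc[base].to_numpy()
            )
            test_rows.append(
                {
                    "comparison": f"{cls}_vs_nochange",
                    "covariate": name,
                    "U": u,
                    "p_value": p,
                    "skipped": False,
                }
            )
    return AssociationReport(
        summary=pd.DataFrame(summary_rows), tests=pd.DataFrame(test_rows)
    )


def cross_species_compare(
    report_a: AssociationReport,
    report_b: AssociationReport,
    lengths_a: pd.Series,
    lengths_b: pd.Series,
    ortholog_map: pd.DataFrame,
) -> dict:
    """Contrast two species runs: affected-gene counts, their ratio, ortholog
    gene-length pairs, and each species' down-vs-nochange length effect.

    ``ortholog_map`` columns: gene_a, gene_b.
    """
    if ortholog_map.empty:
        raise ValueError("ortholog map is empty")

    def counts_of(report: AssociationReport) -> dict:
        s = report.summary.set_index("class")["n"]
        return {"n_down": int(s.get("down", 0)), "n_up": int(s.get("up", 0))}

    ca, cb = counts_of(report_a), counts_of(report_b)
    affected_a = ca["n_down"] + ca["n_up"]
    affected_b = cb["n_down"] + cb["n_up"]

    pairs = ortholog_map.copy()
    pairs["length_a"] = lengths_a.reindex(pairs["gene_a"]).to_numpy()
    pairs["length_b"] = lengths_b.reindex(pairs["gene_b"]).to_numpy()
    pairs = pairs.dropna()

    def length_effect(report: AssociationReport) -> dict:
        t = report.tests
        row = t[(t.comparison == "down_vs_nochange") & (t.covariate == "gene_length")]
        if row.empty:
            return {"p_value": np.nan, "skipped": True}
        r = row.iloc[0]
        return {"p_value": float(r.p_value), "skipped": bool(r.skipped)}

    return {
        "species_a": {**ca, "length_effect": length_effect(report_a)},
        "species_b": {**cb, "length_effect": length_effect(report_b)},
        "affected_ratio_a_over_b": (
            affected_a / affected_b if affected_b else math.inf
        ),
        "ortholog_pairs": pairs,
        "median_length_a": float(np.median(pairs["length_a"])) if len(pairs) else np.nan,
        "median_length_b": float(np.median(pairs["length_b"])) if len(pairs) else np.nan,
    }
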