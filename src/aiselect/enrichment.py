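"""Downstream statistics for called selection events.

Covers four questions about alleles under somatic selection: are they
enriched for predicted-deleterious variants (CADD > 10, hypergeometric
test); do their germline frequencies differ between the cancer cohort and a
control population (Fisher's exact test per allele, then Storey q-values);
do the genes they hit skew toward stronger CRISPR dependency (two-sample
Kolmogorov-Smirnov); and how do the class fractions compare across strata
of increasing significance (percentile bootstrap + Tukey HSD on the
replicate fractions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortCounts
from .significance import storey_qvalues

__all__ = [
    "DELETERIOUS_CADD_CUTOFF",
    "classify_deleterious",
    "hypergeom_enrichment",
    "allele_freq_test",
    "case_allele_frequencies",
    "frequency_calls",
    "ks_dependency_test",
    "bootstrap_fraction_ci",
    "stratified_fraction_comparison",
]

DELETERIOUS_CADD_CUTOFF = 10.0


def classify_deleterious(cadd):
    """Deleterious iff CADD strictly greater than 10."""
    cadd = np.asarray(cadd, dtype=float)
    if np.any(~np.isfinite(cadd)):
        raise ValueError("CADD scores must be finite")
    out = cadd > DELETERIOUS_CADD_CUTOFF
    return out if out.ndim else bool(out)


def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric enrichment p-value P(X >= k) for drawing
    ``k`` flagged items in a selection of size ``n`` from a background of
    ``N`` items of which ``K`` are flagged."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def allele_freq_test(case_b: int, case_total: int,
                     control_b: int, control_total: int) -> float:
    """Two-sided Fisher's exact p for a case/control B-allele 2x2 table."""
    if not (0 <= case_b <= case_total and 0 <= control_b <= control_total):
        raise ValueError("allele counts exceed totals")
    table = [[case_b, case_total - case_b],
             [control_b, control_total - control_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def case_allele_frequencies(cohort: CohortCounts) -> pd.DataFrame:
    """Germline B-allele counts in the case cohort from normal-sample
    genotypes (het = 1 B allele, hom-alt = 2, hom-ref = 0; samples below
    the coverage threshold at a SNP are excluded there)."""
    total = cohort.normal_a + cohort.normal_b
    called = total > 20
    with np.errstate(invalid="ignore"):
        baf = np.where(called, cohort.normal_b / np.maximum(total, 1), np.nan)
    n_b = np.where(called, np.where(baf > 0.8, 2,
                   np.where(baf >= 0.2, 1, 0)), 0)
    case_total = 2 * called.sum(axis=1)
    return pd.DataFrame({
        "snp_id": cohort.loci["snp_id"].to_numpy(),
        "case_b": n_b.sum(axis=1),
        "case_total": case_total,
        "case_af": np.where(case_total > 0, n_b.sum(axis=1) / np.maximum(case_total, 1), np.nan),
    })


def frequency_calls(case: pd.DataFrame, annotations: pd.DataFrame,
                    control_n: int = 699, q_cut: float = 0.05) -> pd.DataFrame:
    """Per-allele case-vs-control frequency comparison.

    Control allele counts are reconstructed from the control population B
    frequency at 2 * ``control_n`` chromosomes; per-SNP Fisher p-values are
    converted to Storey q-values and thresholded at ``q_cut`` to label
    alleles "higher" or "lower" in cancer.
    """
    merged = case.merge(annotations[["snp_id", "control_af"]], on="snp_id")
    control_total = 2 * control_n
    pvals = np.array([
        allele_freq_test(int(r.case_b), int(r.case_total),
                         int(round(r.control_af * control_total)), control_total)
        for r in merged.itertuples()
    ])
    q = storey_qvalues(pvals)
    control_af = merged["control_af"].to_numpy()
    case_af = merged["case_af"].to_numpy()
    label = np.where((q < q_cut) & (case_af > control_af), "higher",
                     np.where((q < q_cut) & (case_af < control_af), "lower",
                              "ns"))
    out = merged[["snp_id", "case_af", "control_af"]].copy()
    out["p"] = pvals
    out["q"] = q
    out["freq_direction"] = label
    return out


def ks_dependency_test(scores_selected, scores_background,
                       alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test of a gene-dependency shift.

    ``alternative="less"`` tests the one-sided "selected scores skew lower"
    direction (their CDF lies above the background's).
    """
    sel = np.asarray(scores_selected, dtype=float)
    bg = np.asarray(scores_background, dtype=float)
    if sel.size == 0 or bg.size == 0:
        raise ValueError("both score collections must be non-empty")
    if alternative == "less":
        res = stats.ks_2samp(sel, bg, alternative="greater")
    elif alternative == "greater":
        res = stats.ks_2samp(sel, bg, alternative="less")
    else:
        res = stats.ks_2samp(sel, bg, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def bootstrap_fraction_ci(member_flags, n_boot: int = 1000,
                          seed: int = 0) -> tuple[float, float, float]:
    """Percentile bootstrap mean and 95% interval of a class fraction."""
    flags = np.asarray(member_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("member_flags must be non-empty")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    reps = rng.binomial(flags.size, flags.mean(), size=n_boot) / flags.size
    return (float(reps.mean()), float(np.percentile(reps, 2.5)),
            float(np.percentile(reps, 97.5)))


def _bootstrap_replicates(flags: np.ndarray, n_boot: int, rng) -> np.ndarray:
    idx = rng.integers(0, flags.size, size=(n_boot, flags.size))
    return flags[idx].mean(axis=1)


def stratified_fraction_comparison(
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    flag_column: str = "deleterious",
    alphas: tuple[float, ...] = (0.05, 0.01, 0.001),
    directions: tuple[str, ...] = ("selected_for", "selected_against"),
    n_boot: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Fraction of flagged alleles per (direction x significance) stratum
    versus the background of all tested alleles.

    Returns the per-stratum table (fraction, background fraction, ratio,
    upper- and lower-tail hypergeometric p) and, when ``n_boot`` > 0, a
    pairwise Tukey-HSD comparison of strata computed on bootstrap replicate
    fractions (background included as its own group). Strata at nested
    significance levels use nested SNP sets by construction.
    """
    merged = calls.merge(annotations, on="snp_id", how="inner")
    if flag_column not in merged.columns:
        raise ValueError(f"no column {flag_column!r} after joining annotations")
    flags_all = merged[flag_column].to_numpy(dtype=bool)
    N, K = flags_all.size, int(flags_all.sum())
    bg_frac = K / N if N else np.nan

    rng = np.random.default_rng(seed)
    rows = []
    groups: dict[str, np.ndarray] = {"background": flags_all}
    for direction in directions:
        for a in sorted(alphas, reverse=True):
            in_stratum = ((merged["direction"] == direction)
                          & merged[f"sig_{a}"]).to_numpy()
            n = int(in_stratum.sum())
            k = int(flags_all[in_stratum].sum())
            frac = k / n if n else np.nan
            p_up = hypergeom_enrichment(k, n, K, N) if n else np.nan
            p_down = float(stats.hypergeom.cdf(k, N, K, n)) if n else np.nan
            rows.append({
                "direction": direction, "level": a, "n_stratum": n,
                "fraction_selected": frac, "fraction_background": bg_frac,
                "ratio": frac / bg_frac if (n and bg_frac) else np.nan,
                "p": p_up, "p_depletion": p_down,
            })
            if n_boot > 0 and n >= 2:
                groups[f"{direction}@{a}"] = flags_all[in_stratum]
    table = pd.DataFrame(rows)

    pairwise = None
    if n_boot > 0 and len(groups) >= 2:
        names = list(groups)
        reps = [_bootstrap_replicates(groups[g], n_boot, rng) for g in names]
        res = stats.tukey_hsd(*reps)
        recs = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                recs.append({
                    "group_a": names[i], "group_b": names[j],
                    "mean_diff": float(np.mean(reps[i]) - np.mean(reps[j])),
                    "p_tukey": float(res.pvalue[i, j]),
                })
        pairwise = pd.DataFrame(recs)
    return table, pairwise
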