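"""Inferential layer: normality gating, per-bin mixed models with FDR,
omnibus/post-hoc tests, effect sizes, and permutation FWER control.

Time-resolved contrasts of co-HFO probability are tested bin by bin with a
linear mixed-effects model ``value ~ condition`` with a random intercept per
subject, fitted by REML; the omnibus condition p-value per bin is a Wald test
on the condition coefficients and pairwise contrasts come from rotating the
condition reference level.  Benjamini-Hochberg FDR is applied across the bins
of each contrast.  A Shapiro-Wilk gate selects parametric
(ANOVA/t) versus nonparametric (Kruskal-Wallis/Wilcoxon) families for scalar
comparisons, with Tukey's HSD for pairwise follow-ups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05


@dataclass
class GateResult:
    family: str              # "parametric" | "nonparametric"
    p_shapiro: float
    flag: str | None = None


@dataclass
class EffectSize:
    d: float
    ci_low: float
    ci_high: float
    flag: str | None = None


def normality_gate(samples, alpha: float = ALPHA) -> GateResult:
    """Shapiro-Wilk test choosing the downstream test family."""
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        return GateResult("nonparametric", float("nan"),
                          flag="n < 3; nonparametric by default")
    if np.ptp(x) == 0:
        return GateResult("nonparametric", float("nan"),
                          flag="degenerate constant sample")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = sps.shapiro(x)
    family = "parametric" if p > alpha else "nonparametric"
    return GateResult(family, float(p))


def fdr_bh(p_values, q: float = ALPHA) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _condition_wald(result) -> float:
    """Two-sided omnibus p for all condition coefficients being zero."""
    names = list(result.params.index)
    idx = [i for i, name in enumerate(names) if "condition" in name]
    if not idx:
        return float("nan")
    k = np.zeros((len(idx), len(names)))
    for row, i in enumerate(idx):
        k[row, i] = 1.0
    try:
        wt = result.wald_test(k, scalar=True)
    except (ValueError, np.linalg.LinAlgError):
        return float("nan")  # saturated/degenerate fit; no test possible
    return float(np.squeeze(wt.pvalue))


def per_bin_lmm(table: pd.DataFrame, q: float = ALPHA,
                pairwise: bool = False) -> pd.DataFrame:
    """Fit ``value ~ condition + (1 | subject)`` independently at each bin.

    ``table`` is long format with columns value, condition, subject, bin.
    Returns one row per bin (per contrast when ``pairwise``) with the Wald
    omnibus p-value for the condition term and an FDR significance flag
    computed across bins within each contrast.  Singular or failed mixed fits
    fall back to a fixed-effects-only OLS fit and are flagged.
    """
    required = {"value", "condition", "subject", "bin"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    conditions = sorted(table["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions")
    single_subject = table["subject"].nunique() < 2
    rows = []
    with warnings.catch_warnings():
        # statsmodels emits numerical RuntimeWarnings from intermediate
        # fits; failures surface through the documented fallback flags
        warnings.simplefilter("ignore", RuntimeWarning)
        for b, sub in table.groupby("bin", sort=True):
            fits = _fit_bin(sub, conditions, single_subject, pairwise)
            for contrast, p, flag in fits:
                rows.append(dict(bin=b, contrast=contrast, p_value=p,
                                 flag=flag))
    out = pd.DataFrame(rows)
    out["q_significant"] = False
    for contrast, grp in out.groupby("contrast"):
        mask = fdr_bh(grp["p_value"].to_numpy(), q=q)
        out.loc[grp.index, "q_significant"] = mask
    return out.reset_index(drop=True)


def _fit_bin(sub: pd.DataFrame, conditions, single_subject: bool,
             pairwise: bool):
    """One bin's omnibus (and optional pairwise) p-values."""
    results = []
    omnibus_p, flag = _lmm_omnibus(sub, reference=conditions[0],
                                   single_subject=single_subject)
    results.append(("omnibus", omnibus_p, flag))
    if pairwise:
        seen = set()
        for ref in conditions:  # reference-level rotation
            p_by_level, flag_r = _lmm_pairwise(sub, ref, single_subject)
            for other, p in p_by_level.items():
                key = tuple(sorted((ref, other)))
                if key in seen:
                    continue
                seen.add(key)
                results.append((f"{key[0]}-vs-{key[1]}", p, flag_r))
    return results


def _formula(reference: str) -> str:
    return f"value ~ C(condition, Treatment(reference='{reference}'))"


def _mixed_fit(sub: pd.DataFrame, reference: str, single_subject: bool):
    """REML mixed fit with documented OLS fallback; returns (result, flag)."""
    import statsmodels.formula.api as smf

    if single_subject:
        res = smf.ols(_formula(reference), data=sub).fit()
        return res, "single subject; fixed-effects-only fit"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = MixedLM.from_formula(_formula(reference), data=sub,
                                         groups=sub["subject"])
            res = model.fit(reml=True)
            if not np.isfinite(res.params).all():
                raise np.linalg.LinAlgError("non-finite mixed fit")
            return res, None
        except (np.linalg.LinAlgError, ValueError):
            res = smf.ols(_formula(reference), data=sub).fit()
            return res, "singular mixed fit; fixed-effects fallback"


def _lmm_omnibus(sub, reference, single_subject):
    res, flag = _mixed_fit(sub, reference, single_subject)
    return _condition_wald(res), flag


def _lmm_pairwise(sub, reference, single_subject):
    res, flag = _mixed_fit(sub, reference, single_subject)
    out = {}
    for name, p in res.pvalues.items():
        if "condition" in name and "[T." in name:
            level = name.split("[T.")[1].rstrip("]")
            out[level] = float(p)
    return out, flag


def omnibus_and_posthoc(groups: dict[str, np.ndarray], paired: bool = False,
                        alpha: float = ALPHA) -> dict:
    """Omnibus comparison of named groups with Tukey HSD follow-ups.

    The Shapiro-Wilk gate (applied to every group) selects one-way ANOVA or
    Kruskal-Wallis for >= 3 groups; with two groups the omnibus reduces to
    the two-sample (or paired / signed-rank) test.  Groups with n < 2 are
    excluded and flagged.
    """
    flags = []
    usable = {}
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            flags.append(f"group {name!r} excluded (n < 2)")
            continue
        usable[name] = v
    if len(usable) < 2:
        raise ValueError("need >= 2 usable groups")
    parametric = all(normality_gate(v, alpha).family == "parametric"
                     for v in usable.values())
    names = sorted(usable)
    arrays = [usable[n] for n in names]
    if len(arrays) == 2:
        a, b = arrays
        if paired:
            stat, p = (sps.ttest_rel(a, b) if parametric
                       else sps.wilcoxon(a, b))
            test = "paired t" if parametric else "wilcoxon signed-rank"
        else:
            if parametric:
                stat, p = sps.ttest_ind(a, b)
                test = "independent t"
            else:
                stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
                test = "mann-whitney U"
    else:
        if parametric:
            stat, p = sps.f_oneway(*arrays)
            test = "one-way ANOVA"
        else:
            stat, p = sps.kruskal(*arrays)
            test = "kruskal-wallis"
    values = np.concatenate(arrays)
    labels = np.concatenate([[n] * len(usable[n]) for n in names])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairwise_rows = []
    for row in tukey.summary().data[1:]:
        pairwise_rows.append(dict(group_a=str(row[0]), group_b=str(row[1]),
                                  meandiff=float(row[2]), p_adj=float(row[3]),
                                  reject=bool(row[6])))
    return dict(test=test, statistic=float(stat), p_value=float(p),
                family="parametric" if parametric else "nonparametric",
                pairwise=pairwise_rows, flags=flags)


def chi2_test(table: np.ndarray) -> dict:
    """Pearson chi-squared test of a contingency table."""
    chi2, p, dof, _ = sps.chi2_contingency(np.asarray(table))
    return dict(chi2=float(chi2), p_value=float(p), dof=int(dof))


def cohen_d(sample_a, sample_b) -> EffectSize:
    """Cohen's d with a normal-approximation 95% confidence interval.

    d = (mean_a - mean_b) / pooled SD; variance of d approximated by
    (na + nb)/(na*nb) + d^2 / (2*(na + nb)).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = a.size, b.size
    if min(na, nb) < 2:
        raise ValueError("need n >= 2 per sample")
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        return EffectSize(float("nan"), float("nan"), float("nan"),
                          flag="zero pooled SD; d undefined")
    d = (a.mean() - b.mean()) / pooled
    se = np.sqrt((na + nb) / (na * nb) + d * d / (2.0 * (na + nb)))
    return EffectSize(float(d), float(d - 1.959964 * se),
                      float(d + 1.959964 * se))


def permutation_fwer(data: np.ndarray, labels, n_perm: int = 10000,
                     seed: int = 0) -> np.ndarray:
    """Max-statistic permutation test across a statistic map.

    ``data`` has shape (n_units, n_cells) and ``labels`` assigns each unit to
    one of two exchangeable groups.  The per-cell statistic is the two-sample
    t value; family-wise corrected p-values are the rank of each observed
    |t| against the permutation null of the maximum |t| over cells.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    lab = np.asarray(labels)
    groups = np.unique(lab)
    if groups.size != 2:
        raise ValueError("labels must define exactly two groups")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation null")
    rng = np.random.default_rng(seed)

    def tmap(assignment):
        g0 = x[assignment == groups[0]]
        g1 = x[assignment == groups[1]]
        n0, n1 = len(g0), len(g1)
        sp = np.sqrt(((n0 - 1) * g0.var(axis=0, ddof=1)
                      + (n1 - 1) * g1.var(axis=0, ddof=1)) / (n0 + n1 - 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (g0.mean(axis=0) - g1.mean(axis=0)) / (
                sp * np.sqrt(1.0 / n0 + 1.0 / n1))
        return np.nan_to_num(t)

    observed = np.abs(tmap(lab))
    null_max = np.empty(n_perm)
    perm = lab.copy()
    for i in range(n_perm):
        rng.shuffle(perm)
        null_max[i] = np.abs(tmap(perm)).max()
    p = (1.0 + (null_max[:, None] >= observed[None, :]).sum(axis=0)) / (n_perm + 1.0)
    return p
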