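"""Nonparametric differential screening of metabolite panels.

Each disease group is compared with the control group per metabolite using
the two-sided Mann–Whitney U test and the two-sample Kolmogorov–Smirnov
test; Benjamini–Hochberg adjustment is applied across metabolites,
separately per test within each contrast.  A metabolite is called
significant for a contrast according to a combination rule (default:
*both* adjusted p-values below α), and metabolites are then partitioned
into disease-A-specific, disease-B-specific, shared, and none.

Exact null distributions are used for small samples (minimum group size
≤ 12, no ties), the tie-corrected normal approximation with continuity
correction otherwise; each result records which branch was taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .profiles import GROUP_A, GROUP_B, GROUP_CONTROL, MetaboliteProfileSet

#: Largest minimum group size for which the exact null distribution is used.
EXACT_N_MAX = 12

COMBINATION_RULES = ("both", "either", "mw_only", "ks_only")

CLASS_A_SPECIFIC = "A_specific"
CLASS_B_SPECIFIC = "B_specific"
CLASS_SHARED = "shared"
CLASS_NONE = "none"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str  # "exact" | "asymptotic" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


def _check_lengths(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ConfigurationError(
            f"need at least 2 observations per group, got {len(x)} and {len(y)}"
        )
    return x, y


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Two-sided Mann–Whitney U test of ``x`` vs ``y``.

    Exact p-value (full null distribution of U) when the smaller group has
    ≤ 12 observations and the pooled sample is tie-free; otherwise the
    normal approximation with midrank tie correction and continuity
    correction.  If all pooled values are identical the comparison is
    degenerate: U sits at the null mean and p = 1.
    """
    x, y = _check_lengths(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(len(x) * len(y) / 2.0, 1.0, "degenerate")
    exact = min(len(x), len(y)) <= EXACT_N_MAX and not _has_ties(x, y)
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return TestResult(float(res.statistic), float(res.pvalue), method)


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test: D = sup |ECDF_x − ECDF_y|.

    Exact p-value when both groups have ≤ 12 tie-free observations,
    asymptotic otherwise (the exact branch is disabled under ties, where
    the exact distribution is biased).
    """
    x, y = _check_lengths(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "degenerate")
    import warnings

    exact = max(len(x), len(y)) <= EXACT_N_MAX and not _has_ties(x, y)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = stats.ks_2samp(
            x, y, alternative="two-sided", method="exact" if exact else "asymp"
        )
    # scipy silently falls back to asymptotics when the exact network
    # algorithm loses precision (p ≈ 1); record the branch actually used
    if any("Exact calculation unsuccessful" in str(w.message) for w in caught):
        exact = False
    return TestResult(
        float(res.statistic), float(res.pvalue), "exact" if exact else "asymptotic"
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ConfigurationError("bh_adjust expects a 1-D p-value vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScreeningResult:
    """Per-(contrast, metabolite) statistics plus the three-way call.

    ``table`` has one row per (contrast, metabolite) with columns
    ``u, mw_p, mw_p_adj, ks_d, ks_p, ks_p_adj, mw_method, ks_method,
    significant``; ``classification`` maps metabolite →
    {A_specific, B_specific, shared, none}.
    """

    table: pd.DataFrame
    classification: pd.Series
    alpha: float
    rule: str
    contrasts: tuple[str, ...] = (GROUP_A, GROUP_B)

    def significant(self, contrast: str) -> list[str]:
        t = self.table
        sel = t[(t["contrast"] == contrast) & t["significant"]]
        return sorted(sel["metabolite"].tolist())

    def classified(self, label: str) -> list[str]:
        return sorted(self.classification[self.classification == label].index)

    def summary(self) -> dict:
        return {
            "alpha": self.alpha,
            "rule": self.rule,
            "n_significant": {c: len(self.significant(c)) for c in self.contrasts},
            "n_shared": len(self.classified(CLASS_SHARED)),
            "n_A_specific": len(self.classified(CLASS_A_SPECIFIC)),
            "n_B_specific": len(self.classified(CLASS_B_SPECIFIC)),
            CLASS_SHARED: self.classified(CLASS_SHARED),
            CLASS_A_SPECIFIC: self.classified(CLASS_A_SPECIFIC),
            CLASS_B_SPECIFIC: self.classified(CLASS_B_SPECIFIC),
        }


def _combine(mw_sig: pd.Series, ks_sig: pd.Series, rule: str) -> pd.Series:
    if rule == "both":
        return mw_sig & ks_sig
    if rule == "either":
        return mw_sig | ks_sig
    if rule == "mw_only":
        return mw_sig
    if rule == "ks_only":
        return ks_sig
    raise ConfigurationError(f"unknown rule {rule!r}; choose from {COMBINATION_RULES}")


def _batched_tests(
    xs: pd.DataFrame, ys: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    """Run both tests on every column of xs vs ys (pairwise NaN removal)."""
    n_m = xs.shape[1]
    u = np.empty(n_m)
    mw_p = np.empty(n_m)
    ks_d = np.empty(n_m)
    ks_p = np.empty(n_m)
    mw_method: list[str] = []
    ks_method: list[str] = []

    xa = xs.to_numpy(dtype=float)
    ya = ys.to_numpy(dtype=float)
    complete = not (np.isnan(xa).any() or np.isnan(ya).any())
    tie_free = True
    if complete:
        pooled = np.concatenate([xa, ya], axis=0)
        for j in range(n_m):
            if len(np.unique(pooled[:, j])) < pooled.shape[0]:
                tie_free = False
                break
    if complete and tie_free and min(xa.shape[0], ya.shape[0]) <= EXACT_N_MAX:
        # fast path: one vectorised exact call per test across metabolites
        mw = stats.mannwhitneyu(
            xa.T, ya.T, alternative="two-sided", method="exact", axis=-1
        )
        ks_exact = max(xa.shape[0], ya.shape[0]) <= EXACT_N_MAX
        ks = stats.ks_2samp(
            xa.T, ya.T, method="exact" if ks_exact else "asymp", axis=-1
        )
        u[:] = mw.statistic
        mw_p[:] = mw.pvalue
        ks_d[:] = ks.statistic
        ks_p[:] = ks.pvalue
        mw_method = ["exact"] * n_m
        ks_method = ["exact" if ks_exact else "asymptotic"] * n_m
    else:
        for j in range(n_m):
            rm = mann_whitney(xa[:, j], ya[:, j])
            rk = ks_two_sample(xa[:, j], ya[:, j])
            u[j], mw_p[j] = rm.statistic, rm.pvalue
            ks_d[j], ks_p[j] = rk.statistic, rk.pvalue
            mw_method.append(rm.method)
            ks_method.append(rk.method)
    return u, mw_p, ks_d, ks_p, mw_method, ks_method


def screen_panel(
    profiles: MetaboliteProfileSet,
    alpha: float = 0.05,
    rule: str = "both",
) -> ScreeningResult:
    """Screen every metabolite in each disease-vs-control contrast.

    BH adjustment runs across metabolites separately per test within each
    contrast.  Missing values are excluded pairwise, so effective sample
    sizes may differ between metabolites.
    """
    if rule not in COMBINATION_RULES:
        raise ConfigurationError(
            f"unknown rule {rule!r}; choose from {COMBINATION_RULES}"
        )
    groups_present = set(profiles.groups)
    if GROUP_CONTROL not in groups_present:
        raise ConfigurationError("panel has no control group")
    contrasts = [g for g in (GROUP_A, GROUP_B) if g in groups_present]
    if not contrasts:
        raise ConfigurationError("panel has no disease group")

    control = profiles.group_matrix(GROUP_CONTROL)
    mets = profiles.metabolite_ids
    rows = []
    sig_by_contrast: dict[str, pd.Series] = {}
    for contrast in contrasts:
        disease = profiles.group_matrix(contrast)
        u, mw_p, ks_d, ks_p, mw_m, ks_m = _batched_tests(disease, control)
        mw_adj = bh_adjust(mw_p)
        ks_adj = bh_adjust(ks_p)
        mw_sig = pd.Series(mw_adj < alpha, index=mets)
        ks_sig = pd.Series(ks_adj < alpha, index=mets)
        sig = _combine(mw_sig, ks_sig, rule)
        sig_by_contrast[contrast] = sig
        for j, m in enumerate(mets):
            rows.append(
                {
                    "contrast": contrast,
                    "metabolite": m,
                    "metabolite_class": profiles.classes[m],
                    "u": u[j],
                    "mw_p": mw_p[j],
                    "mw_p_adj": mw_adj[j],
                    "mw_method": mw_m[j],
                    "ks_d": ks_d[j],
                    "ks_p": ks_p[j],
                    "ks_p_adj": ks_adj[j],
                    "ks_method": ks_m[j],
                    "significant": bool(sig[m]),
                }
            )

    table = pd.DataFrame(rows)
    sig_a = sig_by_contrast.get(GROUP_A, pd.Series(False, index=mets))
    sig_b = sig_by_contrast.get(GROUP_B, pd.Series(False, index=mets))
    classification = pd.Series(CLASS_NONE, index=pd.Index(mets, name="metabolite"))
    classification[sig_a & sig_b] = CLASS_SHARED
    classification[sig_a & ~sig_b] = CLASS_A_SPECIFIC
    classification[~sig_a & sig_b] = CLASS_B_SPECIFIC
    return ScreeningResult(
        table=table,
        classification=classification,
        alpha=alpha,
        rule=rule,
        contrasts=tuple(contrasts),
    )
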