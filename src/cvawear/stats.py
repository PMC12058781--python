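"""Statistical comparison of OFF vs ON physiology and group reactivity.

Implements the gated testing scheme used for the levodopa analyses:

* Paired OFF/ON comparisons on subject means: Shapiro-Wilk normality on
  each state and Levene variance equality decide between a two-sided paired
  t-test and a Wilcoxon signed-rank test; paired Cohen's d =
  mean(diff) / sd(diff) with diff = ON - OFF.
* OH vs no-OH group comparisons of OFF->ON deltas: Shapiro-Wilk decides
  between an independent t-test and Mann-Whitney U; pooled-SD Cohen's d
  with the OH - no-OH sign convention.
* Dose-response: Pearson's r, or Spearman's rho when Shapiro-Wilk rejects
  normality of either variable.
* Repeated at-home transitions: linear mixed models with a random intercept
  per participant (REML), testing the state (or group) fixed effect with a
  large-sample normal approximation; singular fits fall back to OLS with a
  warning, never silently.
* Multiplicity: Benjamini-Hochberg within two marker families — HR/HRV
  {HR, RMSSD, SDNN, LF, HF, LF/HF} and cardiomechanical/vasomotor
  {PEP, LVETi, PEP/LVETi, SCGamp, PPGamp, PAT, PTT} — applied separately
  per analysis set; both raw and adjusted p-values are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st

__all__ = [
    "FAMILIES",
    "StatResult",
    "gate_paired",
    "gate_group",
    "dose_correlation",
    "lmm_state_effect",
    "lmm_group_effect",
    "bh_adjust",
    "run_clinic_analysis",
    "run_home_analysis",
]

FAMILIES = {
    "hr_hrv": ["HR", "RMSSD", "SDNN", "LF", "HF", "LF_HF"],
    "cardiomech_vasc": ["PEP", "LVETi", "PEP_LVETi", "SCGamp", "PPGamp",
                        "PAT", "PTT"],
}

ALPHA_GATE = 0.05


@dataclass
class StatResult:
    marker: str
    family: str
    analysis: str          # paired_state | group_delta | dose_corr | lmm_*
    test: str
    statistic: float
    p_raw: float
    effect_size: float
    n: int
    p_adj: float = float("nan")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("marker", "family", "analysis", "test", "statistic",
                 "p_raw", "p_adj", "effect_size", "n")}


def _family_of(marker: str) -> str:
    for fam, members in FAMILIES.items():
        if marker in members:
            return fam
    raise KeyError(f"marker {marker!r} not in any family")


def _shapiro_ok(x: np.ndarray, alpha: float) -> bool:
    """True when normality is NOT rejected; degenerate data reject."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return st.shapiro(x).pvalue > alpha


# ---------------------------------------------------------------------------
# Gated pairwise / groupwise tests
# ---------------------------------------------------------------------------

def gate_paired(off: np.ndarray, on: np.ndarray, alpha: float = ALPHA_GATE,
                ) -> dict:
    """Paired OFF/ON comparison with the normality/variance gate.

    Wilcoxon signed-rank when Shapiro-Wilk (either state) or Levene rejects
    at ``alpha``; otherwise a paired t-test.  Effect size is paired Cohen's
    d = mean(ON - OFF) / sd(ON - OFF).
    """
    off = np.asarray(off, dtype=float)
    on = np.asarray(on, dtype=float)
    ok = np.isfinite(off) & np.isfinite(on)
    off, on = off[ok], on[ok]
    n = len(off)
    if n < 3:
        raise ValueError("need >= 3 complete pairs")
    diff = on - off
    sd = diff.std(ddof=1)
    d = float(diff.mean() / sd) if sd > 0 else 0.0
    if np.all(diff == 0):
        return {"test": "degenerate", "statistic": 0.0, "p": 1.0,
                "effect_size": 0.0, "n": n}
    normal = _shapiro_ok(off, alpha) and _shapiro_ok(on, alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eq_var = st.levene(off, on).pvalue > alpha if np.ptp(off) or \
            np.ptp(on) else False
    if normal and eq_var:
        res = st.ttest_rel(on, off)
        return {"test": "paired_t", "statistic": float(res.statistic),
                "p": float(res.pvalue), "effect_size": d, "n": n}
    res = st.wilcoxon(on, off, zero_method="wilcox")
    return {"test": "wilcoxon_signed", "statistic": float(res.statistic),
            "p": float(res.pvalue), "effect_size": d, "n": n}


def gate_group(a: np.ndarray, b: np.ndarray, alpha: float = ALPHA_GATE,
               ) -> dict:
    """Independent comparison (a = OH, b = no-OH) gated on normality.

    Mann-Whitney U when Shapiro-Wilk rejects in either group; otherwise a
    two-sided independent t-test.  Pooled-SD Cohen's d, sign a - b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 values")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    d = float((a.mean() - b.mean()) / np.sqrt(sp2)) if sp2 > 0 else 0.0
    if _shapiro_ok(a, alpha) and _shapiro_ok(b, alpha):
        res = st.ttest_ind(a, b)
        return {"test": "indep_t", "statistic": float(res.statistic),
                "p": float(res.pvalue), "effect_size": d, "n": na + nb}
    res = st.mannwhitneyu(a, b, alternative="two-sided")
    return {"test": "mann_whitney", "statistic": float(res.statistic),
            "p": float(res.pvalue), "effect_size": d, "n": na + nb}


def dose_correlation(delta: np.ndarray, dose: np.ndarray,
                     alpha: float = ALPHA_GATE) -> dict:
    """Gated correlation of OFF->ON change with administered dose."""
    delta = np.asarray(delta, dtype=float)
    dose = np.asarray(dose, dtype=float)
    ok = np.isfinite(delta) & np.isfinite(dose)
    delta, dose = delta[ok], dose[ok]
    if len(delta) < 5:
        raise ValueError("need >= 5 pairs")
    if np.ptp(dose) == 0:
        return {"test": "undefined", "statistic": float("nan"),
                "p": float("nan"), "effect_size": float("nan"),
                "n": len(delta)}
    if _shapiro_ok(delta, alpha) and _shapiro_ok(dose, alpha):
        r, p = st.pearsonr(delta, dose)
        return {"test": "pearson", "statistic": float(r), "p": float(p),
                "effect_size": float(r), "n": len(delta)}
    r, p = st.spearmanr(delta, dose)
    return {"test": "spearman", "statistic": float(r), "p": float(p),
            "effect_size": float(r), "n": len(delta)}


# ---------------------------------------------------------------------------
# Mixed models for repeated home transitions
# ---------------------------------------------------------------------------

def _lmm(df: pd.DataFrame, value: str, fixed: str, subject: str,
         reml: bool = True, test_name: str = "lmm") -> dict:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df[[value, fixed, subject]].dropna()
    n_sub = data[subject].nunique()
    if n_sub < 2 or len(data) < 2 * n_sub:
        raise ValueError("need >= 2 subjects with repeated responses")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(f"{value} ~ {fixed}", data,
                                groups=data[subject])
            fit = model.fit(reml=reml, method="lbfgs")
        coef_name = [c for c in fit.params.index
                     if c.startswith(fixed) and c != "Intercept"][0]
        coef = float(fit.params[coef_name])
        se = float(fit.bse[coef_name])
        p = float(fit.pvalues[coef_name])
        singular = not np.isfinite(p) or not np.isfinite(se)
    except Exception:
        singular = True
    if singular:
        warnings.warn("singular mixed-model fit; falling back to OLS on the "
                      "fixed effect (no random intercept)")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols(f"{value} ~ {fixed}", data).fit()
        coef_name = [c for c in ols.params.index
                     if c.startswith(fixed) and c != "Intercept"][0]
        coef = float(ols.params[coef_name])
        se = float(ols.bse[coef_name])
        p = float(ols.pvalues[coef_name])
        test_name = test_name + "_ols_fallback"
    return {"test": test_name, "statistic": coef / se if se > 0 else 0.0,
            "p": p, "effect_size": coef, "se": se,
            "n": len(data)}


def lmm_state_effect(long_df: pd.DataFrame, value: str = "value",
                     state: str = "state", subject: str = "subject",
                     reml: bool = True) -> dict:
    """Fixed state effect (ON - OFF) with a random intercept per subject."""
    df = long_df.copy()
    df["_state"] = (df[state] == "ON").astype(float)
    return _lmm(df, value, "_state", subject, reml, "lmm_state")


def lmm_group_effect(delta_df: pd.DataFrame, value: str = "delta",
                     group: str = "oh", subject: str = "subject",
                     reml: bool = True) -> dict:
    """Fixed group effect (OH - no-OH) on OFF->ON deltas, random intercepts."""
    df = delta_df.copy()
    df["_group"] = df[group].astype(float)
    return _lmm(df, value, "_group", subject, reml, "lmm_group")


# ---------------------------------------------------------------------------
# Multiplicity
# ---------------------------------------------------------------------------

def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one family).

    adj_(i) = min_{j >= i} p_(j) * m / j (sorted order), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def _adjust_by_family(results: list[StatResult]) -> list[StatResult]:
    """BH adjustment within each (analysis, family) set; NaN p pass through."""
    groups: dict[tuple[str, str], list[StatResult]] = {}
    for r in results:
        groups.setdefault((r.analysis, r.family), []).append(r)
    for rs in groups.values():
        finite = [r for r in rs if np.isfinite(r.p_raw)]
        if finite:
            adj = bh_adjust([r.p_raw for r in finite])
            for r, pa in zip(finite, adj):
                r.p_adj = float(pa)
    return results


# ---------------------------------------------------------------------------
# Analysis drivers
# ---------------------------------------------------------------------------

def _markers_in(table: pd.DataFrame) -> list[str]:
    return [m for fam in FAMILIES.values() for m in fam if m in table.columns]


def run_clinic_analysis(marker_table: pd.DataFrame) -> pd.DataFrame:
    """Clinic analysis: paired OFF/ON tests on subject means, OH vs no-OH
    comparison of the OFF->ON deltas, and dose correlations; BH-adjusted
    per family within each analysis set."""
    mt = marker_table
    if mt["subject"].nunique() < 3:
        raise ValueError("analysis refused: fewer than 3 subjects")
    markers = _markers_in(mt)
    means = mt.groupby(["subject", "state"])[markers].mean().reset_index()
    wide = {s: means[means["state"] == s].set_index("subject")
            for s in ("OFF", "ON")}
    meta = mt.groupby("subject").agg(oh=("oh", "first"),
                                     dose_mg=("dose_mg", "first"))
    results: list[StatResult] = []
    for m in markers:
        fam = _family_of(m)
        off = wide["OFF"][m].reindex(meta.index)
        on = wide["ON"][m].reindex(meta.index)
        try:
            g = gate_paired(off.values, on.values)
            results.append(StatResult(m, fam, "paired_state", g["test"],
                                      g["statistic"], g["p"],
                                      g["effect_size"], g["n"]))
        except ValueError:
            pass
        delta = (on - off)
        try:
            g = gate_group(delta[meta["oh"]].values,
                           delta[~meta["oh"]].values)
            results.append(StatResult(m, fam, "group_delta", g["test"],
                                      g["statistic"], g["p"],
                                      g["effect_size"], g["n"]))
        except ValueError:
            pass
        try:
            g = dose_correlation(delta.values, meta["dose_mg"].values)
            results.append(StatResult(m, fam, "dose_corr", g["test"],
                                      g["statistic"], g["p"],
                                      g["effect_size"], g["n"]))
        except ValueError:
            pass
    _adjust_by_family(results)
    return pd.DataFrame([r.as_dict() for r in results])


def run_home_analysis(marker_table: pd.DataFrame) -> pd.DataFrame:
    """Home analysis: per-marker state-effect and group-effect mixed models
    on the repeated per-window rows; BH-adjusted per family."""
    mt = marker_table
    if mt["subject"].nunique() < 3:
        raise ValueError("analysis refused: fewer than 3 subjects")
    markers = _markers_in(mt)
    results: list[StatResult] = []
    for m in markers:
        fam = _family_of(m)
        long_df = mt[["subject", "state", m]].rename(columns={m: "value"})
        try:
            g = lmm_state_effect(long_df)
            results.append(StatResult(m, fam, "lmm_state", g["test"],
                                      g["statistic"], g["p"],
                                      g["effect_size"], g["n"]))
        except (ValueError, IndexError):
            pass
        if "oh" in mt.columns and "window_id" in mt.columns:
            piv = mt.pivot_table(index=["subject", "window_id"],
                                 columns="state", values=m)
            if {"OFF", "ON"} <= set(piv.columns):
                deltas = (piv["ON"] - piv["OFF"]).dropna().reset_index()
                deltas.columns = ["subject", "window_id", "delta"]
                deltas = deltas.merge(
                    mt.groupby("subject")["oh"].first().reset_index(),
                    on="subject")
                if deltas["oh"].nunique() == 2:
                    try:
                        g = lmm_group_effect(deltas)
                        results.append(StatResult(
                            m, fam, "lmm_group", g["test"], g["statistic"],
                            g["p"], g["effect_size"], g["n"]))
                    except (ValueError, IndexError):
                        pass
    _adjust_by_family(results)
    return pd.DataFrame([r.as_dict() for r in results])
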