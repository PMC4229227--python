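"""Nonparametric group-comparison battery for small twin-design cohorts.

Endpoints are compared across the four treatment groups with the
tie-corrected Kruskal-Wallis rank-sum test; when it rejects at alpha=0.05,
pairwise two-sided Mann-Whitney U tests are run with a Bonferroni
correction (default m = all 6 pairs among 4 groups).  Associations between
endpoints use Spearman's rank correlation, with an exact permutation
p-value at small n.  The twin structure is checked with a fixed-effects
block decomposition (treatment group + ewe) reporting the ewe term's share
of the total sum of squares and its F-test p-value; when that share is
near zero the unblocked nonparametric tests are justified.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "PairwiseResult",
    "CorrelationResult",
    "EweEffectResult",
    "kruskal_wallis",
    "pairwise_mwu_bonferroni",
    "spearman",
    "ewe_effect",
    "run_full_battery",
]

ALPHA = 0.05
EXACT_MWU_MAX_PRODUCT = 400
EXACT_SPEARMAN_MAX_N = 9


@dataclass(frozen=True)
class GroupComparison:
    endpoint: str
    H: float
    df: int
    p: float
    group_summaries: dict[str, tuple[int, float, float]]  # name -> (n, mean, sd)


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    U: float
    p_raw: float
    p_adj: float
    m: int
    method: str


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    undefined: bool = False
    method: str = "t"


@dataclass(frozen=True)
class EweEffectResult:
    """Twin-structure check for one endpoint.

    ``r2_ewe`` is the raw share of the total sum of squares absorbed by the
    ewe blocking factor; with few animals per ewe it soaks up its degrees
    of freedom even under the null (for twins, roughly half the residual
    SS), so ``icc_ewe`` — a method-of-moments variance-component intraclass
    correlation, near zero when litter membership carries no information —
    is the better "is there a ewe effect" summary, alongside the F-test p.
    """

    endpoint: str
    r2_ewe: float
    icc_ewe: float
    p: float
    n_ewes: int
    n_informative_ewes: int
    underpowered: bool = False


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, Mapping):
        items = groups.items()
    else:
        items = ((f"group_{i+1}", g) for i, g in enumerate(groups))
    out = {}
    for name, vals in items:
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name} is empty")
        out[str(name)] = arr
    if len(out) < 2:
        raise ValueError("need at least two groups")
    return out


def kruskal_wallis(groups, endpoint: str = "") -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with chi-square p on k-1 df.

    A completely constant dataset is reported as H = 0, p = 1 rather than
    an error.
    """
    g = _as_groups(groups)
    pooled = np.concatenate(list(g.values()))
    k = len(g)
    if np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*g.values())
    summaries = {
        name: (int(v.size), float(v.mean()),
               float(v.std(ddof=1)) if v.size > 1 else 0.0)
        for name, v in g.items()
    }
    return GroupComparison(endpoint=endpoint, H=float(H), df=k - 1,
                           p=float(p), group_summaries=summaries)


def _mwu(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U: exact when small and tie-free, otherwise
    the tie-corrected normal approximation with continuity correction."""
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and a.size * b.size <= EXACT_MWU_MAX_PRODUCT:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if math.isnan(p):  # degenerate: zero variance under the tie correction
        p = 1.0
    return float(res.statistic), p, method


def pairwise_mwu_bonferroni(groups, pairs: Sequence[tuple[str, str]] | None = None,
                            m: int | None = None) -> list[PairwiseResult]:
    """Bonferroni-corrected pairwise two-sided Mann-Whitney U tests.

    ``m`` is the number of comparisons corrected for; by default every
    pair among the groups (the conservative reading), even when ``pairs``
    restricts which contrasts are actually computed.
    """
    g = _as_groups(groups)
    names = list(g)
    all_pairs = list(itertools.combinations(names, 2))
    if pairs is None:
        pairs = all_pairs
    else:
        for pa, pb in pairs:
            if pa not in g or pb not in g:
                raise ValueError(f"unknown group in pair ({pa}, {pb})")
    if m is None:
        m = len(all_pairs)
    if m < len(pairs):
        raise ValueError("m must be at least the number of pairs tested")
    out = []
    for pa, pb in pairs:
        U, p_raw, method = _mwu(g[pa], g[pb])
        out.append(PairwiseResult(
            pair=(pa, pb), U=U, p_raw=p_raw,
            p_adj=min(1.0, m * p_raw), m=m, method=method))
    return out


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (Pearson on mid-ranks).

    For n <= 9 without the degenerate case the two-sided p-value is exact,
    from full enumeration of rank permutations; otherwise the usual
    t-distribution approximation is used.  Zero variance in either vector
    yields an undefined (flagged) result.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = int(xa.size)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return CorrelationResult(rho=float("nan"), p=float("nan"), n=n,
                                 undefined=True, method="undefined")
    rx = _midranks(xa)
    ry = _midranks(ya)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        p = _spearman_exact_p(rx, ry, rho)
        method = "exact"
    else:
        p = float(sps.spearmanr(xa, ya).pvalue)
        method = "t"
    return CorrelationResult(rho=rho, p=p, n=n, method=method)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """P(|rho| >= |rho_obs|) over all permutations of one rank vector."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(np.dot(rx_c, rx_c)) * float(np.dot(ry_c, ry_c)))
    rhos = (rx_c[perms] @ ry_c) / denom
    tol = 1e-12
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - tol))


def ewe_effect(values, ewe_ids, groups, endpoint: str = "") -> EweEffectResult:
    """Blocked ANOVA check of the twin (ewe) effect on one endpoint.

    Fits a fixed-effects decomposition with treatment group entered first
    and ewe second (Type I sequential sums of squares) and reports
    ``r2_ewe = SS_ewe / SS_total`` with the F-test p-value for the ewe
    term.  Requires at least two ewes with two or more fetuses; with fewer
    the result is flagged underpowered, and with no multi-fetus ewe at all
    there is no within-ewe information and an error is raised.
    """
    import pandas as pd
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    v = np.asarray(values, dtype=float)
    ewe = np.asarray(ewe_ids)
    grp = np.asarray(groups)
    if not (v.size == ewe.size == grp.size):
        raise ValueError("values, ewe_ids and groups must be equally long")
    _, counts = np.unique(ewe, return_counts=True)
    n_multi = int(np.sum(counts >= 2))
    if n_multi == 0:
        raise ValueError("every animal is a singleton ewe: "
                         "no within-ewe information")
    df = pd.DataFrame({"value": v, "ewe": ewe, "group": grp})
    fit = ols("value ~ C(group) + C(ewe)", data=df).fit()
    tab = anova_lm(fit, typ=1)
    ss = tab["sum_sq"]
    ss_total = float(ss.sum())
    ss_ewe = float(ss.get("C(ewe)", 0.0))
    p = float(tab.loc["C(ewe)", "PR(>F)"]) if "C(ewe)" in tab.index else float("nan")
    r2 = ss_ewe / ss_total if ss_total > 0 else 0.0
    # method-of-moments variance components for the ICC
    ms_ewe = float(tab.loc["C(ewe)", "mean_sq"]) if "C(ewe)" in tab.index else 0.0
    ms_res = float(tab.loc["Residual", "mean_sq"])
    n_total = v.size
    k0 = (n_total - float(np.sum(counts ** 2)) / n_total) / max(1, counts.size - 1)
    sigma2_ewe = max(0.0, (ms_ewe - ms_res) / k0) if k0 > 0 else 0.0
    icc = sigma2_ewe / (sigma2_ewe + ms_res) if (sigma2_ewe + ms_res) > 0 else 0.0
    return EweEffectResult(
        endpoint=endpoint,
        r2_ewe=float(np.clip(r2, 0.0, 1.0)),
        icc_ewe=float(icc),
        p=p,
        n_ewes=int(counts.size),
        n_informative_ewes=n_multi,
        underpowered=n_multi < 2,
    )


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BatteryConfig:
    alpha: float = ALPHA
    bonferroni_m: int | None = None       # None -> all pairs among the groups
    pairs: tuple[tuple[str, str], ...] | None = None
    correlation_pairs: tuple[tuple[str, str], ...] | None = None  # endpoint pairs
    run_ewe_check: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def run_full_battery(records, config: BatteryConfig | None = None) -> dict:
    """Kruskal-Wallis per endpoint, gated post-hoc pairwise tests, Spearman
    correlations between endpoints, and the ewe-effect check.

    ``records`` is a sequence of :class:`~wmiquant.synthetic.AnimalRecord`.
    Returns a JSON-serialisable report mirroring the per-group summary format:
    per endpoint the H/df/p, group n/mean/SD, and (if the omnibus test
    rejects) Bonferroni-adjusted pairwise p-values.
    """
    if config is None:
        config = BatteryConfig()
    records = list(records)
    group_names = sorted({r.group for r in records})
    if len(group_names) < 2:
        raise ValueError("need at least two groups present")
    endpoints = sorted({ep for r in records for ep in r.endpoints})

    candidate_pairs = list(itertools.combinations(group_names, 2))
    report: dict = {
        "alpha": config.alpha,
        "groups": group_names,
        "candidate_pairs": [list(p) for p in candidate_pairs],
        "endpoints": {},
        "correlations": {},
    }

    by_group: dict[str, dict[str, list[float]]] = {}
    for ep in endpoints:
        by_group[ep] = {g: [] for g in group_names}
        for r in records:
            if ep in r.endpoints:
                by_group[ep][r.group].append(r.endpoints[ep])

    for ep in endpoints:
        groups = {g: v for g, v in by_group[ep].items() if v}
        kw = kruskal_wallis(groups, endpoint=ep)
        entry: dict = {
            "H": kw.H, "df": kw.df, "p": kw.p,
            "groups": {g: {"n": s[0], "mean": s[1], "sd": s[2]}
                       for g, s in kw.group_summaries.items()},
            "pairwise": None,
        }
        if kw.p < config.alpha:
            pw = pairwise_mwu_bonferroni(groups, pairs=config.pairs,
                                         m=config.bonferroni_m)
            entry["pairwise"] = [{
                "pair": list(r.pair), "U": r.U, "p_raw": r.p_raw,
                "p_adj": r.p_adj, "m": r.m, "method": r.method,
            } for r in pw]
        if config.run_ewe_check:
            ewe_ids = [r.ewe_id for r in records if ep in r.endpoints]
            grp = [r.group for r in records if ep in r.endpoints]
            vals = [r.endpoints[ep] for r in records if ep in r.endpoints]
            counts = np.unique(ewe_ids, return_counts=True)[1]
            if np.any(counts >= 2):
                ee = ewe_effect(vals, ewe_ids, grp, endpoint=ep)
                entry["ewe_effect"] = {
                    "r2_ewe": ee.r2_ewe, "icc_ewe": ee.icc_ewe, "p": ee.p,
                    "underpowered": ee.underpowered,
                }
            else:
                entry["ewe_effect"] = None
        report["endpoints"][ep] = entry

    corr_pairs = (config.correlation_pairs
                  if config.correlation_pairs is not None
                  else tuple(itertools.combinations(endpoints, 2)))
    for ea, eb in corr_pairs:
        xs, ys = [], []
        for r in records:
            if ea in r.endpoints and eb in r.endpoints:
                xs.append(r.endpoints[ea])
                ys.append(r.endpoints[eb])
        if len(xs) < 3:
            continue
        cr = spearman(xs, ys)
        report["correlations"][f"{ea}~{eb}"] = {
            "rho": None if cr.undefined else cr.rho,
            "p": None if cr.undefined else cr.p,
            "n": cr.n, "method": cr.method,
        }
    return report
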