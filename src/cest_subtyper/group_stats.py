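"""Nonparametric group-comparison layer, implemented from first principles.

Contains the exact sign test, exact/approximate Mann-Whitney U,
Kruskal-Wallis with tie correction, the Conover-Iman rank post hoc with
Holm adjustment, Fisher's exact test (probability-mass two-tailed
convention), the Shapiro-Wilk normality screen (Royston's approximation),
and ROC analysis with nearest-to-(0,1) cut points. scipy is used only for
reference distributions (normal, t, chi-square, hypergeometric pmf) and
ranking — the test statistics and p-value conventions are authored here
so they can be validated against independent enumeration oracles.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import AgreementResult

__all__ = [
    "sign_test", "mann_whitney", "kruskal_wallis", "conover_iman",
    "fisher_exact", "shapiro_wilk", "roc_analysis", "holm_adjust",
    "run_group_comparisons", "abfs_t2flair_agreement", "ab_vs_fs_report",
    "RocResult",
]

ALPHA = 0.05


# --------------------------------------------------------------------------
# Elementary exact tests
# --------------------------------------------------------------------------

def sign_test(differences: Sequence[float]) -> float:
    """Exact two-tailed sign test on paired differences.

    Ties (zero differences) are dropped; p = min(1, 2*P(X >= max(n+, n-)))
    with X ~ Binomial(n+ + n-, 1/2).
    """
    d = np.asarray(differences, dtype=float)
    n_pos = int((d > 0).sum())
    n_neg = int((d < 0).sum())
    n = n_pos + n_neg
    if n == 0:
        raise ValueError("no informative pairs (all differences zero)")
    k = max(n_pos, n_neg)
    # P(X >= k) for X ~ Bin(n, 1/2), summed exactly over binomial weights
    tail = sum(math.comb(n, j) for j in range(k, n + 1)) / 2.0 ** n
    return min(1.0, 2.0 * tail)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """U statistic of x (number of (x, y) pairs won by x, ties 1/2)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[: x.size].sum()
    u_x = r_x - x.size * (x.size + 1) / 2.0
    return u_x, ranks


def _exact_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U (counts) by dynamic programming.

    count[u] = number of arrangements of n1 ranks among n1+n2 with
    U = u; equivalent to enumerating all C(n1+n2, n1) labelings.
    """
    max_u = n1 * n2
    # f[j][u]: number of ways to choose j ranks producing U = u
    f = np.zeros((n1 + 1, max_u + 1), dtype=float)
    f[0, 0] = 1.0
    for i in range(1, n1 + n2 + 1):          # process ranks in order
        for j in range(min(i, n1), 0, -1):
            # choosing rank i as the j-th x adds (i - j) to U
            add = i - j
            if add > max_u:
                continue
            f[j, add:] += f[j - 1, : max_u + 1 - add]
    return f[n1]


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 exact_threshold: int = 10) -> Tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns (U_x, p).

    Exact p by full enumeration of the rank-assignment null when
    min(n) <= exact_threshold and there are no ties; otherwise a normal
    approximation with tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    u_x, ranks = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    has_ties = np.unique(np.concatenate([x, y])).size < n1 + n2
    if min(n1, n2) <= exact_threshold and not has_ties:
        counts = _exact_u_distribution(n1, n2)
        total = counts.sum()
        u_lo = min(u_x, n1 * n2 - u_x)
        p = min(1.0, 2.0 * counts[: int(round(u_lo)) + 1].sum() / total)
        return float(u_x), float(p)
    # tie-corrected normal approximation with continuity correction
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return float(u_x), 1.0
    z = (abs(u_x - mu) - 0.5) / math.sqrt(var)
    return float(u_x), float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with chi-square p on k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start: start + a.size]
        h += r.sum() ** 2 / a.size
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    if correction <= 0:          # all values identical
        return 0.0, 1.0
    h /= correction
    p = float(sps.chi2.sf(h, len(arrays) - 1))
    return float(h), p


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def conover_iman(groups: Sequence[Sequence[float]],
                 kw_result: Optional[Tuple[float, float]] = None,
                 adjust: str = "holm", override_gate: bool = False
                 ) -> pd.DataFrame:
    """Conover-Iman pairwise rank comparisons after Kruskal-Wallis.

    t_ij = (Rbar_i - Rbar_j) / sqrt(S2 * (N-1-H)/(N-k) * (1/n_i + 1/n_j))
    referenced to Student's t with N-k df; S2 = (sum R^2 - N(N+1)^2/4)/(N-1).
    Gate: requires the Kruskal-Wallis p < 0.05 unless ``override_gate``.
    """
    if adjust not in ("holm", "bonferroni", "none"):
        raise ValueError("adjust must be holm, bonferroni or none")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if kw_result is None:
        kw_result = kruskal_wallis(arrays)
    h, kw_p = kw_result
    if kw_p >= ALPHA and not override_gate:
        raise ValueError("Kruskal-Wallis not significant at 0.05; "
                         "set override_gate=True to force the post hoc")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0] + sizes)
    rbar = [ranks[bounds[i]: bounds[i + 1]].mean() for i in range(k)]
    s2 = ((ranks ** 2).sum() - n * (n + 1) ** 2 / 4.0) / (n - 1)
    scale = s2 * (n - 1 - h) / (n - k)
    df = n - k
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(max(scale, 0.0) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        t = (rbar[i] - rbar[j]) / se if se > 0 else 0.0
        p = float(min(1.0, 2.0 * sps.t.sf(abs(t), df)))
        rows.append({"i": i, "j": j, "t": t, "p_raw": p})
    table = pd.DataFrame(rows)
    if adjust == "holm":
        table["p_adj"] = holm_adjust(table["p_raw"].to_numpy())
    elif adjust == "bonferroni":
        table["p_adj"] = np.minimum(1.0, table["p_raw"] * len(table))
    else:
        table["p_adj"] = table["p_raw"]
    table.attrs["adjust"] = adjust
    table.attrs["gated"] = bool(kw_p < ALPHA)
    return table


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher's exact test, probability-mass convention.

    p = sum of hypergeometric probabilities of all tables with the same
    margins whose probability <= that of the observed table (with a
    numerical slack of 1e-7). A zero margin returns p = 1 by convention.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    # exact integer arithmetic on hypergeometric weights
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = {x: math.comb(r1, x) * math.comb(n - r1, c1 - x)
               for x in range(lo, hi + 1)}
    w_obs = weights[int(a)]
    num = sum(w for w in weights.values() if w <= w_obs * (1.0 + 1e-7))
    return min(1.0, num / math.comb(n, c1))


# --------------------------------------------------------------------------
# Shapiro-Wilk screen (Royston's approximation)
# --------------------------------------------------------------------------

_SW_C1 = (-2.706056, 4.434685, -2.071190, -0.147981, 0.221157)
_SW_C2 = (-3.582633, 5.682633, -1.752461, -0.293762, 0.042981)


def shapiro_wilk(sample: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 50, via Royston's polynomials.

    Used only as a screen motivating the nonparametric track; the result
    is reported, never used to gate any computation.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if not 3 <= n <= 50:
        raise ValueError("Shapiro-Wilk screen supports 3 <= n <= 50")
    if x[-1] - x[0] <= 0:
        raise ValueError("sample has zero range")
    m = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    mm = float(m @ m)
    c = m / math.sqrt(mm)
    u = 1.0 / math.sqrt(n)
    a_n = (((((_SW_C1[0] * u + _SW_C1[1]) * u + _SW_C1[2]) * u
             + _SW_C1[3]) * u + _SW_C1[4]) * u) + c[-1]
    a = np.empty(n)
    if n <= 5:
        phi = (mm - 2.0 * m[-1] ** 2) / (1.0 - 2.0 * a_n ** 2)
        a[1:-1] = m[1:-1] / math.sqrt(phi)
        a[-1], a[0] = a_n, -a_n
    else:
        a_n1 = (((((_SW_C2[0] * u + _SW_C2[1]) * u + _SW_C2[2]) * u
                  + _SW_C2[3]) * u + _SW_C2[4]) * u) + c[-2]
        phi = (mm - 2.0 * m[-1] ** 2 - 2.0 * m[-2] ** 2) \
            / (1.0 - 2.0 * a_n ** 2 - 2.0 * a_n1 ** 2)
        a[2:-2] = m[2:-2] / math.sqrt(phi)
        a[-1], a[0] = a_n, -a_n
        a[-2], a[1] = a_n1, -a_n1
    w = float((a @ x) ** 2 / ((x - x.mean()) ** 2).sum())
    w = min(w, 1.0 - 1e-15)
    if n == 3:
        p = 6.0 / math.pi * (math.asin(math.sqrt(w)) - math.asin(math.sqrt(0.75)))
        return w, float(np.clip(p, 0.0, 1.0))
    if n < 12:
        g = -2.273 + 0.459 * n
        mu = 0.5440 - 0.39978 * n + 0.025054 * n ** 2 - 0.0006714 * n ** 3
        sig = math.exp(1.3822 - 0.77857 * n + 0.062767 * n ** 2
                       - 0.0020322 * n ** 3)
        z = (-math.log(g - math.log1p(-w)) - mu) / sig
    else:
        ln_n = math.log(n)
        mu = 0.0038915 * ln_n ** 3 - 0.083751 * ln_n ** 2 - 0.31082 * ln_n - 1.5861
        sig = math.exp(0.0030302 * ln_n ** 2 - 0.082676 * ln_n - 0.4803)
        z = (math.log1p(-w) - mu) / sig
    return w, float(sps.norm.sf(z))


# --------------------------------------------------------------------------
# ROC analysis
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    cut_point: float
    sensitivity: float
    specificity: float
    direction: str        # "greater": positives score above the cut point


def roc_analysis(scores: Sequence[float], labels: Sequence[int],
                 direction: str = "auto") -> RocResult:
    """AUC by pair counting (ties count 1/2) and nearest-to-(0,1) cut point.

    Candidate thresholds are midpoints between consecutive distinct scores
    plus +/-inf; classification is strict '>' on the oriented score. If the
    raw AUC is below 0.5 and direction is 'auto' the orientation is flipped
    (recorded in ``direction``).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    pos, neg = s[y], s[~y]
    total = pos.size * neg.size
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    u_pos = wins + 0.5 * ties                 # Mann-Whitney U of the positives
    auc = u_pos / total
    flip = direction == "less" or (direction == "auto" and auc < 0.5)
    if flip:
        s = -s
        auc = (total - u_pos) / total         # exact counterpart of 1 - auc
        pos, neg = -pos, -neg
    uniq = np.unique(s)
    cands = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    best = None
    for thr in cands:
        sens = float((pos > thr).mean())
        spec = float((neg <= thr).mean())
        dist = math.hypot(1.0 - sens, 1.0 - spec)
        key = (round(dist, 12), -sens, thr)
        if best is None or key < best[0]:
            best = (key, thr, sens, spec)
    _, thr, sens, spec = best
    cut = -thr if flip else thr
    return RocResult(auc=float(auc), cut_point=float(cut),
                     sensitivity=sens, specificity=spec,
                     direction="less" if flip else "greater")


# --------------------------------------------------------------------------
# Report assembly
# --------------------------------------------------------------------------

from .roi_metrics import METRIC_COLUMNS  # noqa: E402  (table layout shared)

PARTITIONS = ("two", "three", "four")


def _partition_groups(table: pd.DataFrame, partition: str) -> Dict[str, np.ndarray]:
    """Row masks of the groups of one partition of the cohort table."""
    idh = table["idh"].astype(str)
    codel = table["codel"].astype(str)
    mm = table["abfs_mismatch"].astype(bool)
    if partition == "two":
        groups = {"IDH-wt": idh == "wt", "IDH-mut": idh == "mut"}
    elif partition == "three":
        groups = {"IDH-wt": idh == "wt",
                  "IDHmut-ret": (idh == "mut") & (codel == "ret"),
                  "IDHmut-codel": (idh == "mut") & (codel == "codel")}
    elif partition == "four":
        groups = {"IDH-wt": idh == "wt",
                  "IDHmut-ret-mm": (idh == "mut") & (codel == "ret") & mm,
                  "IDHmut-ret-nomm": (idh == "mut") & (codel == "ret") & ~mm,
                  "IDHmut-codel": (idh == "mut") & (codel == "codel")}
    else:
        raise ValueError(f"unknown partition '{partition}'")
    for name, mask in groups.items():
        if mask.sum() < 2:
            raise ValueError(f"partition '{partition}': group '{name}' has "
                             f"fewer than 2 subjects")
    return {k: v.to_numpy() for k, v in groups.items()}


def _metric_values(table: pd.DataFrame, metric: str, mask: np.ndarray) -> np.ndarray:
    vals = table.loc[mask, metric].to_numpy(dtype=float)
    return vals[np.isfinite(vals)]        # flagged ratios dropped pairwise


def run_group_comparisons(table: pd.DataFrame,
                          partitions: Sequence[str] = PARTITIONS,
                          adjust: str = "holm",
                          exact_threshold: int = 10,
                          alpha: float = ALPHA) -> pd.DataFrame:
    """Table-1-shaped report: per partition and metric, the appropriate
    rank test; ROC appended for pairs significant after adjustment."""
    rows: List[dict] = []
    for partition in partitions:
        groups = _partition_groups(table, partition)
        names = list(groups)
        for metric in METRIC_COLUMNS:
            samples = {g: _metric_values(table, metric, m)
                       for g, m in groups.items()}
            if any(v.size < 2 for v in samples.values()):
                continue
            if partition == "two":
                pairs = [(names[0], names[1], None)]
                _, p_omni = mann_whitney(samples[names[0]], samples[names[1]],
                                         exact_threshold)
                omni_test = "mann-whitney"
            else:
                h, p_omni = kruskal_wallis([samples[g] for g in names])
                omni_test = "kruskal-wallis"
                pairs = []
                if p_omni < alpha:
                    ci = conover_iman([samples[g] for g in names],
                                      kw_result=(h, p_omni), adjust=adjust)
                    for _, r in ci.iterrows():
                        pairs.append((names[int(r["i"])], names[int(r["j"])],
                                      float(r["p_adj"])))
            for ga, gb, p_pair in pairs:
                if partition == "two":
                    p = p_omni
                else:
                    p = p_pair
                row = {"partition": partition, "metric": metric,
                       "group_a": ga, "group_b": gb,
                       "test": omni_test, "p_omnibus": p_omni, "p": p,
                       "significant": p < alpha}
                if p < alpha:
                    x, yv = samples[ga], samples[gb]
                    scores = np.concatenate([x, yv])
                    lbl = np.concatenate([np.ones(x.size, int),
                                          np.zeros(yv.size, int)])
                    roc = roc_analysis(scores, lbl)
                    row.update({"auc": roc.auc, "cut_point": roc.cut_point,
                                "sensitivity": roc.sensitivity,
                                "specificity": roc.specificity,
                                "direction": f"{ga} {'>' if roc.direction == 'greater' else '<'} {gb}"})
                else:
                    row.update({"auc": np.nan, "cut_point": np.nan,
                                "sensitivity": np.nan, "specificity": np.nan,
                                "direction": ""})
                rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["adjust"] = adjust
    out.attrs["exact_threshold"] = exact_threshold
    out.attrs["alpha"] = alpha
    return out


def ab_vs_fs_report(table: pd.DataFrame) -> pd.DataFrame:
    """Table-3-shaped report: sign tests of AB vs FS per group and channel.

    The NAWM row uses the per-subject NAWM-ROI AB-FS values across the
    whole cohort; tumour rows use the normalized AB-FS metrics. The
    amide/amine-ratio channel is reported for tumour rows only.
    """
    idh = table["idh"].astype(str)
    codel = table["codel"].astype(str)
    mm = table["abfs_mismatch"].astype(bool)
    groupings = [
        ("NAWM", np.ones(len(table), dtype=bool)),
        ("IDH-wt", (idh == "wt").to_numpy()),
        ("IDH-mut", (idh == "mut").to_numpy()),
        ("IDHmut-ret", ((idh == "mut") & (codel == "ret")).to_numpy()),
        ("IDHmut-codel", ((idh == "mut") & (codel == "codel")).to_numpy()),
        ("IDHmut-ret-mm", ((idh == "mut") & (codel == "ret") & mm).to_numpy()),
        ("IDHmut-ret-nomm", ((idh == "mut") & (codel == "ret") & ~mm).to_numpy()),
    ]
    rows = []
    for name, mask in groupings:
        if mask.sum() == 0:
            continue
        if name == "NAWM":
            channels = {"abfs_amide": "nawm_abfs_amide",
                        "abfs_amine": "nawm_abfs_amine"}
        else:
            channels = {c: c for c in ("abfs_amide", "abfs_amine", "abfs_ratio")}
        row: Dict[str, object] = {"group": name, "n": int(mask.sum())}
        for chan, col in channels.items():
            vals = table.loc[mask, col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"{chan}_median"] = float(np.median(vals)) if vals.size else np.nan
            row[f"{chan}_q25"] = float(np.percentile(vals, 25)) if vals.size else np.nan
            row[f"{chan}_q75"] = float(np.percentile(vals, 75)) if vals.size else np.nan
            try:
                row[f"{chan}_p"] = sign_test(vals)
            except ValueError:
                row[f"{chan}_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def abfs_t2flair_agreement(table: pd.DataFrame,
                           channels: Sequence[str] = ("abfs_amide", "abfs_amine"),
                           rule: str = "amine",
                           restrict_to_retained: bool = True,
                           use_derived_cuts: bool = True,
                           fixed_thresholds: Tuple[float, float] = (0.039, 0.18)
                           ) -> AgreementResult:
    """AB/FS-mismatch vs T2/FLAIR-mismatch agreement.

    Restricted by default to the IDH-mutant 1p/19q-retained subgroup (the
    population in which T2/FLAIR mismatch occurs). Per channel, a ROC
    against the T2/FLAIR label yields the surrogate cut point with its
    sensitivity/specificity; the binary AB/FS-mismatch call then uses the
    configured rule with the derived (default) or fixed cut points, and
    agreement is assessed by Fisher's exact test on the 2x2 table.
    """
    sub = table
    if restrict_to_retained:
        sub = table[(table["idh"] == "mut") & (table["codel"] == "ret")]
    t2 = sub["t2flair_mismatch"].astype(bool).to_numpy()
    if t2.sum() == 0:
        raise ValueError("no positive T2/FLAIR labels in the restriction")
    if (~t2).sum() == 0:
        raise ValueError("no negative T2/FLAIR labels in the restriction")
    chan_results: Dict[str, dict] = {}
    thresholds: Dict[str, float] = {}
    for chan, fixed in zip(("abfs_amide", "abfs_amine"), fixed_thresholds):
        if chan not in channels:
            continue
        scores = sub[chan].to_numpy(dtype=float)
        roc = roc_analysis(scores, t2.astype(int))
        thresholds[chan] = roc.cut_point if use_derived_cuts else fixed
        chan_results[chan] = {
            "auc": roc.auc, "cut_point": roc.cut_point,
            "sensitivity": roc.sensitivity, "specificity": roc.specificity,
            "threshold_used": thresholds[chan],
        }
    def call(row) -> bool:
        pos_d = row["abfs_amide"] > thresholds.get("abfs_amide", np.inf)
        pos_n = row["abfs_amine"] > thresholds.get("abfs_amine", np.inf)
        return {"amine": pos_n, "amide": pos_d,
                "either": pos_d or pos_n, "both": pos_d and pos_n}[rule]
    mismatch = sub.apply(call, axis=1).to_numpy(dtype=bool)
    contingency = np.array([
        [int((mismatch & t2).sum()), int((mismatch & ~t2).sum())],
        [int((~mismatch & t2).sum()), int((~mismatch & ~t2).sum())],
    ])
    p = fisher_exact(contingency)
    return AgreementResult(contingency=contingency, fisher_p=p,
                           channels=chan_results, rule=rule, n=len(sub))
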