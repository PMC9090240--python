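"""Disease-activity (DAS28) methylation analysis.

DAS28 is a composite disease-activity score; its standard clinical
categories are remission (< 2.6), low (2.6-3.2], moderate (3.2-5.1] and
high (> 5.1) — the printed interval endpoints overlap, so this package
closes the upper end of each interval.

The genome-wide screen correlates per-probe beta values with DAS28 by
Spearman's rank correlation and retains probes passing joint cutoffs
(|rho| >= 0.7 AND p <= 1e-3 by default).  Cross-compartment concordance of
the retained sets (blood vs synovial fluid) is tested by Fisher's exact
test over the probe universe.  Reversion analysis relates each patient's
change in mean methylation over a CpG set between two visits to their
change in DAS28.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import MethylationMatrix, zscore_rows
from .enrichment import fisher_exact_2x2

CATEGORIES = ("remission", "low", "moderate", "high")

#: permutation-exact Spearman p for n at or below this size
EXACT_SPEARMAN_N = 9


def categorize_das28(value) -> str | None:
    """DAS28 activity category; closed upper interval ends.

    remission: v < 2.6; low: 2.6 <= v <= 3.2; moderate: 3.2 < v <= 5.1;
    high: v > 5.1.  Missing values map to None.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    v = float(value)
    if v < 0:
        raise ValueError("DAS28 must be nonnegative")
    if v < 2.6:
        return "remission"
    if v <= 3.2:
        return "low"
    if v <= 5.1:
        return "moderate"
    return "high"


def category_index(category: str | None) -> float:
    """Ordinal index of a category (remission=0 .. high=3); NaN if missing."""
    if category is None:
        return float("nan")
    return float(CATEGORIES.index(category))


def _exact_spearman_p(rho_obs: float, ranks_y: np.ndarray,
                      ranks_x: np.ndarray) -> float:
    """Exact two-sided permutation p for Spearman rho at small n."""
    n = ranks_x.size
    perms = np.array(list(permutations(range(n))))
    permuted = ranks_y[perms]  # all orderings of y ranks
    rx = (ranks_x - ranks_x.mean())
    ry = permuted - permuted.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        rhos = (ry @ rx) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho on mid-ranks with a two-sided p-value.

    p uses the t transform t = rho * sqrt((n-2) / (1-rho^2)) with n-2 df;
    for n <= 9 the exact permutation distribution is used instead.
    |rho| = 1 gives p = 0 (asymptotic) or the exact tail at small n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("spearman requires n >= 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), 1.0
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_N:
        p = _exact_spearman_p(rho, ry, rx)
    elif abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return rho, p


@dataclass
class ActivityCorrelation:
    """Per-probe methylation-activity correlation surviving the cutoffs."""

    probe_id: str
    rho: float
    p: float

    @property
    def sign(self) -> str:
        return "+" if self.rho > 0 else "-"


def correlate_activity(matrix: MethylationMatrix, sample_sheet: pd.DataFrame,
                       rho_min: float = 0.7,
                       p_max: float = 1e-3) -> pd.DataFrame:
    """Genome-wide Spearman screen of beta vs DAS28.

    Only samples with a DAS28 value enter.  Returns a DataFrame indexed by
    probe id with rho, p and sign for probes passing |rho| >= rho_min AND
    p <= p_max.  The computation is rank-based and vectorized; the per-probe
    p uses the t approximation (n is comfortably above the exact-p regime
    in any real screen).
    """
    sheet = sample_sheet.set_index("sample_id")
    eligible = sheet.index[sheet["das28"].notna()]
    eligible = [s for s in eligible if s in matrix.sample_ids]
    if len(eligible) == 0:
        raise ValueError("no samples with DAS28 available")
    if len(eligible) < 5:
        raise ValueError("need >= 5 samples with DAS28")
    das = sheet.loc[eligible, "das28"].to_numpy(dtype=float)
    beta = matrix.beta[eligible].to_numpy()
    n = das.size

    ranks_y = sps.rankdata(das)
    ranks_x = np.apply_along_axis(sps.rankdata, 1, beta)
    rx = ranks_x - ranks_x.mean(axis=1, keepdims=True)
    ry = ranks_y - ranks_y.mean()
    denom = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry) / denom
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0 - 1e-15, 0.0, p)
    out = pd.DataFrame({"rho": rho, "p": p},
                       index=matrix.probe_ids.rename("probe_id"))
    out = out[np.isfinite(out["rho"])]
    out = out[(out["rho"].abs() >= rho_min) & (out["p"] <= p_max)]
    out["sign"] = np.where(out["rho"] > 0, "+", "-")
    return out


def compartment_concordance(corr_blood: pd.DataFrame, corr_sf: pd.DataFrame,
                            universe) -> dict:
    """Fisher concordance of correlated-CpG membership across compartments.

    Returns log2 odds ratio and p of the 2x2 (correlated in blood) x
    (correlated in SF) table over the probe universe, plus the fraction of
    blood-correlated CpGs also SF-correlated, overall and per sign.
    """
    universe = pd.Index(universe)
    in_blood = universe.isin(corr_blood.index)
    in_sf = universe.isin(corr_sf.index)
    if not in_blood.any() or not in_sf.any():
        warnings.warn("empty correlated set; concordance degenerate",
                      stacklevel=2)
    a = int(np.sum(in_blood & in_sf))
    b = int(np.sum(in_blood & ~in_sf))
    c = int(np.sum(~in_blood & in_sf))
    d = int(np.sum(~in_blood & ~in_sf))
    odds, p = fisher_exact_2x2(a, b, c, d)
    shared = {}
    for sign in ("+", "-"):
        ids = corr_blood.index[corr_blood["sign"] == sign]
        if len(ids) == 0:
            shared[sign] = float("nan")
        else:
            shared[sign] = float(np.mean(ids.isin(corr_sf.index)))
    shared_all = float(np.mean(corr_blood.index.isin(corr_sf.index))) \
        if len(corr_blood) else float("nan")
    return {
        "a": a, "b": b, "c": c, "d": d,
        "odds_ratio": odds,
        "log2_odds_ratio": float(np.log2(odds)) if odds and np.isfinite(odds)
        else (float("inf") if odds == np.inf else float("nan")),
        "p": p,
        "shared_fraction": shared_all,
        "shared_fraction_by_sign": shared,
    }


def reversion_analysis(matrix_v1: MethylationMatrix,
                       matrix_v4: MethylationMatrix,
                       sample_sheet: pd.DataFrame,
                       cpg_set,
                       use_zscore: bool = True):
    """Per-patient change in mean methylation vs change in DAS28.

    For every subject present at both visits, computes the mean over
    ``cpg_set`` of (z-scored) beta at the later visit minus the earlier, the
    matching DAS28 change, and the shift in activity-category index, then
    the Spearman correlation of the two deltas across subjects.

    Returns ``(records, rho, p)`` where records is a DataFrame with one row
    per subject.  Positively and negatively DAS28-correlated CpG sets should
    be passed in separately.
    """
    cpg_set = pd.Index(cpg_set)
    if len(cpg_set) == 0:
        raise ValueError("cpg_set is empty")
    sheet = sample_sheet.set_index("sample_id")

    def _mean_profile(matrix):
        found = cpg_set.intersection(matrix.probe_ids)
        beta = matrix.beta.loc[found]
        vals = zscore_rows(beta) if use_zscore else beta
        return vals.mean(axis=0)

    prof1 = _mean_profile(matrix_v1)
    prof4 = _mean_profile(matrix_v4)
    subj1 = {sheet.loc[s, "subject_id"]: s for s in prof1.index if s in sheet.index}
    subj4 = {sheet.loc[s, "subject_id"]: s for s in prof4.index if s in sheet.index}
    both = sorted(set(subj1) & set(subj4))
    dropped = (set(subj1) | set(subj4)) - set(both)
    if dropped:
        warnings.warn(f"{len(dropped)} subjects missing one visit; excluded",
                      stacklevel=2)
    rows = []
    for subj in both:
        s1, s4 = subj1[subj], subj4[subj]
        das1 = sheet.loc[s1, "das28"]
        das4 = sheet.loc[s4, "das28"]
        cat1 = category_index(categorize_das28(das1))
        cat4 = category_index(categorize_das28(das4))
        rows.append({
            "subject_id": subj,
            "delta_mean_meth": float(prof4[s4] - prof1[s1]),
            "delta_das28": float(das4 - das1)
            if pd.notna(das1) and pd.notna(das4) else float("nan"),
            "category_shift": int(cat4 - cat1)
            if not (math.isnan(cat1) or math.isnan(cat4)) else 0,
        })
    records = pd.DataFrame(rows)
    dm = records["delta_mean_meth"].to_numpy()
    dd = records["delta_das28"].to_numpy()
    ok = np.isfinite(dm) & np.isfinite(dd)
    if ok.sum() >= 4 and np.ptp(dm[ok]) > 0 and np.ptp(dd[ok]) > 0:
        rho, p = spearman(dm[ok], dd[ok])
    else:
        warnings.warn("reversion correlation undefined (constant or tiny "
                      "delta vectors)", stacklevel=2)
        rho, p = float("nan"), float("nan")
    return records, rho, p
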