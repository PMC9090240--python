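"""Per-probe differential methylation on M-values.

Each probe is fitted by (weighted) ordinary least squares against a design
built from the sample sheet — a two-group contrast or a three-group one-way
layout, optionally with numeric covariates (e.g. DAS28) and a subject
pairing factor.  Residual variances are shrunk toward a common prior by the
empirical-Bayes scaled-inverse-chi-square model: the prior degrees of
freedom d0 and prior variance s0^2 are estimated by matching moments of
log s_g^2 (digamma/trigamma inversion), and the posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces s_g^2 in the t statistic, which is referred to a t distribution
with d0 + d_g degrees of freedom.  Per-sample reliability weights are
estimated from probe-wise residual variability when requested.

Effect sizes (delta-beta) are reported on the beta scale as the difference
of group mean betas (contrast group minus reference); a probe is "hyper"
when delta-beta > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .core import MethylationMatrix
from .stats import bh_adjust

__all__ = [
    "DesignSpec",
    "ModerationParams",
    "bh_adjust",
    "build_design",
    "estimate_sample_weights",
    "moderated_t_test",
    "call_dmps",
    "top_k_dmps",
    "group_dmrs",
]


@dataclass(frozen=True)
class DesignSpec:
    """Which contrast to fit, over which sample-sheet column.

    ``contrast`` is (reference, contrast) for a two-group comparison or a
    3-tuple for an any-difference moderated F layout.  ``covariates`` are
    numeric sample-sheet fields adjusted for; ``pairing`` names a field
    (normally ``subject_id``) expanded to per-subject blocking dummies.
    """

    contrast: tuple
    contrast_field: str = "group"
    covariates: tuple = ()
    pairing: str | None = None

    def __post_init__(self):
        if len(self.contrast) not in (2, 3):
            raise ValueError("contrast must name 2 or 3 levels")
        object.__setattr__(self, "contrast", tuple(self.contrast))
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass
class ModerationParams:
    """Fitted empirical-Bayes hyperparameters and per-probe variances."""

    d0: float
    s0_sq: float
    s_sq: np.ndarray = field(repr=False)
    df_residual: float = 0.0

    def __post_init__(self):
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def build_design(sample_sheet: pd.DataFrame, spec: DesignSpec):
    """Build the design matrix and locate the contrast column(s).

    Returns ``(X, contrast_cols, samples)`` where ``X`` is a DataFrame of
    regressors over the samples belonging to the contrast levels and
    ``contrast_cols`` are the column names whose coefficients carry the
    group effect (one for a pairwise contrast, two for a 3-level layout).
    """
    levels = list(spec.contrast)
    fld = spec.contrast_field
    present = set(sample_sheet[fld].astype(str))
    missing = [g for g in levels if str(g) not in present]
    if missing:
        raise ValueError(f"contrast levels absent from sample sheet: {missing}")
    mask = sample_sheet[fld].astype(str).isin([str(g) for g in levels])
    sheet = sample_sheet[mask]
    cols = {"Intercept": np.ones(len(sheet))}
    contrast_cols = []
    for lev in levels[1:]:
        name = f"{fld}[{lev}]"
        cols[name] = (sheet[fld].astype(str) == str(lev)).to_numpy(float)
        contrast_cols.append(name)
    for cov in spec.covariates:
        vals = pd.to_numeric(sheet[cov], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"covariate {cov!r} has missing values in contrast samples")
        cols[cov] = vals.to_numpy(float)
    if spec.pairing is not None:
        if (sheet.groupby(spec.pairing).size() < 2).all() and len(sheet) > 1:
            raise ValueError("pairing requires >=2 samples for some subject")
        dummies = pd.get_dummies(sheet[spec.pairing].astype(str),
                                 prefix=spec.pairing, drop_first=True)
        for dname in dummies.columns:
            cols[dname] = dummies[dname].to_numpy(float)
    X = pd.DataFrame(cols, index=sheet["sample_id"].to_numpy())
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, contrast_cols, sheet


def estimate_sample_weights(matrix_m: pd.DataFrame, design: pd.DataFrame,
                            max_iter: int = 50, tol: float = 1e-6) -> pd.Series:
    """Estimate per-sample reliability weights from probe-wise residuals.

    Iteratively reweighted scheme: starting from unit weights, each round
    fits weighted OLS per probe, sets the sample variance factor gamma_j to
    the mean standardized squared residual of sample j across probes,
    normalizes gamma to geometric mean 1, and uses 1/gamma as the next
    weights, until the relative change falls below ``tol``.
    """
    X = design.to_numpy(dtype=float)
    Y = matrix_m[design.index].to_numpy(dtype=float)  # probes x samples
    n, p = X.shape
    if n - p < 3:
        raise ValueError("need >=3 residual degrees of freedom for weights")
    gamma = np.ones(n)
    for _ in range(max_iter):
        w = 1.0 / gamma
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        Q, _ = np.linalg.qr(Xw)
        leverage = np.minimum((Q ** 2).sum(axis=1), 1.0 - 1e-8)
        Yw = Y * sw[None, :]
        resid_w = Yw - Yw @ Q @ Q.T
        s_sq = (resid_w ** 2).sum(axis=1) / (n - p)
        s_sq = np.maximum(s_sq, 1e-12)
        # E[r_wj^2] = (gamma_j / gamma_old_j) * sigma_g^2 * (1 - h_j), so the
        # leverage-standardized mean residual is a multiplicative correction
        stdized = resid_w ** 2 / (s_sq[:, None] * (1.0 - leverage)[None, :])
        correction = stdized.mean(axis=0)
        new_gamma = gamma * correction ** 0.8  # damped update
        new_gamma = np.clip(new_gamma, 1e-3, 1e3)
        new_gamma /= np.exp(np.mean(np.log(new_gamma)))
        change = np.max(np.abs(new_gamma - gamma) / gamma)
        gamma = new_gamma
        if change < tol:
            break
    else:
        warnings.warn("sample-weight estimation did not converge; "
                      "returning last iterate", stacklevel=2)
    return pd.Series(1.0 / gamma, index=design.index, name="weight")


def _trigamma_inverse(x: float, tol: float = 1e-8) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_variance_prior(s_sq: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log residual variances to a scaled-F model.

    Returns (d0, s0_sq).  d0 may be +inf when the observed spread of
    log-variances does not exceed what sampling alone predicts.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    ok = s_sq > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s_sq[ok])) if ok.any() else 1.0
    z = np.log(s_sq[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = float(np.mean(s_sq[ok]))
    return float(d0), float(s0_sq)


def _t_sf2(t: np.ndarray, df: float) -> np.ndarray:
    """Two-sided p from |t| with possibly infinite df."""
    if np.isinf(df):
        return 2.0 * sps.norm.sf(np.abs(t))
    return 2.0 * sps.t.sf(np.abs(t), df)


def moderated_t_test(
    matrix: MethylationMatrix,
    sample_sheet: pd.DataFrame,
    spec: DesignSpec,
    weights: pd.Series | None = None,
    s0_sq_fixed: float | None = None,
    d0_fixed: float | None = None,
):
    """Empirical-Bayes moderated t (or F) test per probe.

    For a two-level contrast returns a DMP table with the M-scale contrast
    coefficient, delta-beta, moderated t, p, BH-adjusted FDR and direction.
    For a three-level layout an any-difference moderated F is computed over
    the two group coefficients; delta-beta then contrasts the last level
    against the first.

    ``weights`` are per-sample reliability weights (see
    :func:`estimate_sample_weights`); ``d0_fixed``/``s0_sq_fixed`` override
    the fitted prior (used for closed-form checks).
    """
    sample_sheet = sample_sheet[
        sample_sheet["sample_id"].isin(matrix.sample_ids)]
    X_df, contrast_cols, sheet = build_design(sample_sheet, spec)
    X = X_df.to_numpy(dtype=float)
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("zero residual degrees of freedom")
    M = matrix.m[X_df.index].to_numpy(dtype=float)
    if weights is not None:
        w = weights.reindex(X_df.index).to_numpy(dtype=float)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be positive and cover all samples")
    else:
        w = np.ones(n)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    coefs = M * sw[None, :] @ Xw @ XtX_inv.T  # probes x p
    fitted_w = coefs @ Xw.T
    resid_w = M * sw[None, :] - fitted_w
    s_sq = (resid_w ** 2).sum(axis=1) / df_resid

    if d0_fixed is not None or s0_sq_fixed is not None:
        if d0_fixed is None or s0_sq_fixed is None:
            raise ValueError("fix both d0 and s0_sq or neither")
        d0, s0_sq = float(d0_fixed), float(s0_sq_fixed)
    else:
        d0, s0_sq = fit_variance_prior(s_sq, df_resid)
    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
    else:
        s_tilde_sq = (d0 * s0_sq + df_resid * s_sq) / (d0 + df_resid)
    df_total = d0 + df_resid

    idx = [X_df.columns.get_loc(c) for c in contrast_cols]
    if len(idx) == 1:
        j = idx[0]
        coef = coefs[:, j]
        v = XtX_inv[j, j]
        t_mod = coef / np.sqrt(s_tilde_sq * v)
        pvals = _t_sf2(t_mod, df_total)
        stat = t_mod
    else:  # moderated F across group coefficients
        B = coefs[:, idx]  # probes x r
        V = XtX_inv[np.ix_(idx, idx)]
        Vinv = np.linalg.inv(V)
        quad = np.einsum("gi,ij,gj->g", B, Vinv, B)
        r = len(idx)
        f_mod = quad / (r * s_tilde_sq)
        if np.isinf(df_total):
            pvals = sps.chi2.sf(r * f_mod, r)
        else:
            pvals = sps.f.sf(f_mod, r, df_total)
        coef = B[:, -1]  # last level vs reference, for direction
        stat = f_mod

    # delta-beta: difference of group mean betas, contrast minus reference
    fld = spec.contrast_field
    ref, alt = str(spec.contrast[0]), str(spec.contrast[-1])
    grp = sheet.set_index("sample_id")[fld].astype(str)
    beta = matrix.beta[X_df.index]
    mean_ref = beta.loc[:, grp[grp == ref].index].mean(axis=1)
    mean_alt = beta.loc[:, grp[grp == alt].index].mean(axis=1)
    delta_beta = (mean_alt - mean_ref).to_numpy()

    table = pd.DataFrame(
        {
            "coef": coef,
            "delta_beta": delta_beta,
            "t": stat,
            "p": pvals,
            "fdr": bh_adjust(pvals),
            "direction": np.where(delta_beta > 0, "hyper", "hypo"),
        },
        index=matrix.probe_ids.rename("probe_id"),
    )
    params = ModerationParams(d0=d0, s0_sq=s0_sq, s_sq=s_sq,
                              df_residual=df_resid)
    return table, params


def call_dmps(dmp_table: pd.DataFrame, fdr_max: float = 0.05,
              min_abs_delta_beta: float = 0.0) -> pd.DataFrame:
    """Retain probes with fdr < fdr_max and |delta-beta| >= the cutoff."""
    keep = (dmp_table["fdr"] < fdr_max) & (
        dmp_table["delta_beta"].abs() >= min_abs_delta_beta
    )
    return dmp_table[keep.fillna(False)]


def top_k_dmps(dmp_table: pd.DataFrame, k: int = 1000) -> list:
    """The k most significant probes, ordered by p ascending.

    Ties on p are broken by |t| descending, then probe id lexicographic, so
    the selection is deterministic under input permutation.
    """
    if k > len(dmp_table):
        warnings.warn(f"top_k_dmps: k={k} exceeds table size {len(dmp_table)}; "
                      "returning all probes", stacklevel=2)
        k = len(dmp_table)
    order = dmp_table.assign(
        _abs_t=dmp_table["t"].abs(), _pid=dmp_table.index.astype(str)
    ).sort_values(["p", "_abs_t", "_pid"], ascending=[True, False, True],
                  kind="mergesort")
    return list(order.index[:k])


def group_dmrs(dmps: pd.DataFrame, annotation: pd.DataFrame,
               max_gap_bp: int = 1000, min_probes: int = 2) -> pd.DataFrame:
    """Chain same-chromosome, same-direction DMPs into regions.

    Single-linkage: consecutive DMPs (by position) join one chain while the
    gap is <= ``max_gap_bp`` and the direction matches; chains with
    >= ``min_probes`` probes are reported with their span and mean
    delta-beta.
    """
    ann = annotation.set_index("probe_id")
    found = dmps.index.intersection(ann.index)
    d = dmps.loc[found].join(ann.loc[found, ["chrom", "pos"]])
    d = d.sort_values(["chrom", "pos"], kind="mergesort")
    regions = []
    chain: list = []

    def flush(chain):
        if len(chain) >= min_probes:
            regions.append(
                {
                    "chrom": chain[0][1],
                    "start": chain[0][2],
                    "end": chain[-1][2],
                    "n_probes": len(chain),
                    "mean_delta_beta": float(np.mean([c[3] for c in chain])),
                    "direction": chain[0][4],
                    "probe_ids": ",".join(c[0] for c in chain),
                }
            )

    for pid, row in d.iterrows():
        rec = (pid, row["chrom"], int(row["pos"]), row["delta_beta"],
               row["direction"])
        if chain and (rec[1] != chain[-1][1] or rec[4] != chain[-1][4]
                      or rec[2] - chain[-1][2] > max_gap_bp):
            flush(chain)
            chain = []
        chain.append(rec)
    flush(chain)
    return pd.DataFrame(
        regions,
        columns=["chrom", "start", "end", "n_probes", "mean_delta_beta",
                 "direction", "probe_ids"],
    )


def write_dmp_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_dmp_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")
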