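"""Methylation matrix container, transforms, filtering and normalization.

The central object is :class:`MethylationMatrix`: an ordered probes x samples
matrix of beta values (methylated fraction, in [0, 1]) with a logit-scale
M-value view (M = log2(beta / (1 - beta))).  Inference downstream runs on
M-values, whose distribution is far closer to Gaussian than the bounded,
heteroskedastic beta values; betas are kept for effect sizes and display.

Side tables follow the array convention: a probe annotation (CpG id,
chromosome, 1-based position, SNP-overlap flag) and a sample sheet carrying
the clinical design (subject, group HD/GP/PP, compartment blood/SF, visit,
DAS28, DMARD treatment flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Clipping constant keeping logit(beta) finite.
BETA_EPS = 1e-6

GROUPS = ("HD", "GP", "PP")
COMPARTMENTS = ("blood", "SF")
SEX_CHROMS = ("chrX", "chrY")

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "subject_id",
    "group",
    "compartment",
    "visit",
    "das28",
    "treated_dmard",
]

ANNOTATION_COLUMNS = ["probe_id", "chrom", "pos", "snp_overlap"]


class MatrixError(ValueError):
    """Raised when a methylation matrix violates its invariants."""


@dataclass
class MethylationMatrix:
    """Probes x samples beta-value matrix with aligned identifiers.

    Parameters
    ----------
    beta
        DataFrame indexed by probe id with sample ids as columns; all values
        finite and in [0, 1].
    """

    beta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        beta = self.beta
        if beta.index.has_duplicates:
            dup = beta.index[beta.index.duplicated()][0]
            raise MatrixError(f"duplicated probe id: {dup!r}")
        if beta.columns.has_duplicates:
            dup = beta.columns[beta.columns.duplicated()][0]
            raise MatrixError(f"duplicated sample id: {dup!r}")
        values = beta.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = beta.index[np.where(~np.isfinite(values))[0][0]]
            raise MatrixError(f"non-finite beta value at probe {bad!r}")
        if values.size and (values.min() < 0.0 or values.max() > 1.0):
            bad = beta.index[np.where((values < 0) | (values > 1))[0][0]]
            raise MatrixError(f"beta out of [0, 1] at probe {bad!r}")
        self.beta = beta.astype(float)

    # -- basic accessors ---------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def m(self) -> pd.DataFrame:
        """M-value view: log2(beta / (1 - beta)) with clipped endpoints."""
        return pd.DataFrame(
            beta_to_m(self.beta.to_numpy()),
            index=self.beta.index,
            columns=self.beta.columns,
        )

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.beta.loc[probe_ids])

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.beta[list(sample_ids)])

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.beta.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "MethylationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)


def beta_to_m(beta, eps: float = BETA_EPS):
    """Convert beta values to M-values, M = log2(beta / (1 - beta)).

    Values at 0/1 are clipped to (eps, 1 - eps) so the logit stays finite.
    """
    arr = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("beta_to_m: non-finite input")
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("beta_to_m: input outside [0, 1]")
    clipped = np.clip(arr, eps, 1.0 - eps)
    out = np.log2(clipped / (1.0 - clipped))
    return out if arr.ndim else float(out)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2**M / (2**M + 1)."""
    arr = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("m_to_beta: non-finite input")
    out = 1.0 / (1.0 + np.exp2(-arr))
    return out if arr.ndim else float(out)


# ---------------------------------------------------------------------------
# Probe filtering
# ---------------------------------------------------------------------------

def filter_probes(
    matrix: MethylationMatrix,
    annotation: pd.DataFrame,
    drop_snp: bool = True,
    drop_sex: bool = True,
    detection_fail_ids=None,
) -> MethylationMatrix:
    """Remove SNP-coincident probes, sex-chromosome probes and detection failures.

    CpGs that coincide with an SNP locus confound the methylation signal with
    genotype; chrX/chrY probes are dropped to avoid sex-driven discordancy
    between samples.  ``detection_fail_ids`` is a caller-supplied list of
    probes that failed detection (p >= 0.01 on the intensity scale); the
    computation of detection p-values itself requires raw intensities and is
    not performed here.  Probe order is preserved.
    """
    ann = validate_annotation(annotation)
    missing = matrix.probe_ids.difference(ann["probe_id"])
    if len(missing):
        raise MatrixError(
            f"annotation does not cover {len(missing)} matrix probes "
            f"(first: {missing[0]!r})"
        )
    ann = ann.set_index("probe_id").loc[matrix.probe_ids]
    keep = pd.Series(True, index=matrix.probe_ids)
    if drop_snp:
        keep &= ~ann["snp_overlap"].astype(bool)
    if drop_sex:
        keep &= ~ann["chrom"].isin(SEX_CHROMS)
    if detection_fail_ids is not None:
        fail = pd.Index(detection_fail_ids)
        unknown = fail.difference(matrix.probe_ids)
        if len(unknown):
            warnings.warn(
                f"{len(unknown)} detection-fail ids not in matrix; ignored",
                stacklevel=2,
            )
        keep &= ~matrix.probe_ids.isin(fail)
    return MethylationMatrix(matrix.beta.loc[keep[keep].index])


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: MethylationMatrix) -> MethylationMatrix:
    """Force every sample onto the across-sample mean distribution.

    Each column's sorted values are replaced by the mean of the order
    statistics across samples; tied values within a column receive the mean
    of the reference quantiles their ranks span.  Rank order within each
    column is preserved.
    """
    if matrix.n_samples < 2:
        warnings.warn("quantile_normalize: single sample, returned unchanged",
                      stacklevel=2)
        return matrix
    x = matrix.beta.to_numpy()
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty_like(reference)
        ranked[order] = reference
        # average reference quantiles over ties
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [col.size]])
        if starts.size < col.size:  # ties present
            csum = np.concatenate([[0.0], np.cumsum(reference)])
            tie_means = (csum[ends] - csum[starts]) / (ends - starts)
            expanded = np.repeat(tie_means, ends - starts)
            ranked[order] = expanded
        out[:, j] = ranked
    return MethylationMatrix(
        pd.DataFrame(out, index=matrix.probe_ids, columns=matrix.sample_ids)
    )


# ---------------------------------------------------------------------------
# Row scaling and covariate adjustment
# ---------------------------------------------------------------------------

def zscore_rows(values: pd.DataFrame, grouping=None) -> pd.DataFrame:
    """Z-score each row, independently within each batch of columns.

    Uses the sample (n - 1) standard deviation.  Rows with zero variance in
    a batch get z-scores of 0 with a warning.
    """
    if grouping is None:
        grouping = pd.Series("all", index=values.columns)
    else:
        grouping = pd.Series(list(grouping), index=values.columns)
    out = values.astype(float).copy()
    warned = False
    for _, cols in grouping.groupby(grouping):
        block = out[cols.index].to_numpy()
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        zero = sd[:, 0] == 0
        if zero.any() and not warned:
            warnings.warn(
                f"zscore_rows: {int(zero.sum())} zero-variance rows set to 0",
                stacklevel=2,
            )
            warned = True
        sd[sd == 0] = 1.0
        z = (block - mean) / sd
        z[zero, :] = 0.0
        out[cols.index] = z
    return out


def adjust_covariates(
    matrix_m: pd.DataFrame,
    covariates: pd.DataFrame,
    keep_effects,
) -> pd.DataFrame:
    """Regress out nuisance covariates from an M-value matrix.

    Per probe, fits OLS of M on the full design (kept effects plus nuisance
    columns) and subtracts only the fitted nuisance contribution, so the
    kept effects survive untouched.  Categorical covariates are expanded to
    treatment-coded dummies; an intercept is always retained.
    """
    keep_effects = list(keep_effects)
    unknown = [c for c in keep_effects if c not in covariates.columns]
    if unknown:
        raise ValueError(f"keep_effects not in covariates: {unknown}")
    design_parts = {"Intercept": np.ones(len(covariates))}
    col_role: dict[str, str] = {"Intercept": "keep"}
    for name in covariates.columns:
        role = "keep" if name in keep_effects else "nuisance"
        col = covariates[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for dname in dummies.columns:
                design_parts[dname] = dummies[dname].to_numpy(dtype=float)
                col_role[dname] = role
        else:
            design_parts[name] = col.to_numpy(dtype=float)
            col_role[name] = role
    design = pd.DataFrame(design_parts, index=covariates.index)
    X = design.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a minimal collinear set by dropping columns until full rank
        collinear = []
        cols = list(design.columns)
        for i, c in enumerate(cols):
            sub = design.drop(columns=collinear + [c]).to_numpy()
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(c)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    Y = matrix_m[design.index].to_numpy().T  # samples x probes
    coefs, *_ = np.linalg.lstsq(X, Y, rcond=None)
    nuisance_idx = [i for i, c in enumerate(design.columns)
                    if col_role[c] == "nuisance"]
    fitted_nuisance = X[:, nuisance_idx] @ coefs[nuisance_idx, :]
    adjusted = (Y - fitted_nuisance).T
    return pd.DataFrame(adjusted, index=matrix_m.index, columns=design.index)


# ---------------------------------------------------------------------------
# Side-table validation and I/O
# ---------------------------------------------------------------------------

def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    ann = annotation.reset_index() if annotation.index.name == "probe_id" else annotation
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise MatrixError(f"annotation missing columns: {missing}")
    if ann["probe_id"].duplicated().any():
        dup = ann.loc[ann["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise MatrixError(f"annotation has duplicated probe id {dup!r}")
    if (ann["pos"] < 1).any():
        row = ann.index[ann["pos"] < 1][0]
        raise MatrixError(f"annotation row {row}: pos < 1")
    return ann


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise MatrixError(f"sample sheet missing columns: {missing}")
    bad_group = ~sheet["group"].isin(GROUPS)
    if bad_group.any():
        row = sheet.index[bad_group][0]
        raise MatrixError(f"sample sheet row {row}: unknown group")
    bad_comp = ~sheet["compartment"].isin(COMPARTMENTS)
    if bad_comp.any():
        row = sheet.index[bad_comp][0]
        raise MatrixError(f"sample sheet row {row}: unknown compartment")
    hd_with_das = (sheet["group"] == "HD") & sheet["das28"].notna()
    if hd_with_das.any():
        row = sheet.index[hd_with_das][0]
        raise MatrixError(f"sample sheet row {row}: HD sample carries a DAS28")
    key = sheet[["subject_id", "compartment", "visit"]]
    if key.duplicated().any():
        row = sheet.index[key.duplicated()][0]
        raise MatrixError(
            f"sample sheet row {row}: duplicate (subject, compartment, visit)"
        )
    return sheet


def read_annotation(path) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, sep="\t"))


def write_annotation(annotation: pd.DataFrame, path) -> None:
    validate_annotation(annotation).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    sheet["treated_dmard"] = sheet["treated_dmard"].astype(bool)
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet).to_csv(path, sep="\t", index=False)
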