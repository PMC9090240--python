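"""Seeded synthetic longitudinal two-compartment methylome cohort.

Emulates the statistical structure a monocyte methylome study of early
undifferentiated arthritis (UA) presents to the analysis code:

* healthy donors (HD) sampled once; patients split into good-prognosis (GP)
  and poor-prognosis (PP) groups, sampled in blood over up to four visits,
  with a synovial-fluid (SF) sample at baseline for a subset;
* UA-vs-HD differential positions with a strong hypermethylation bias
  (~90% of planted effects positive on the beta scale);
* prognosis positions with cumulative effects (HD < GP < PP: GP shifted by
  delta, PP by 2*delta);
* per-visit multiplicative decay of planted effects (reversion toward the
  healthy baseline, group-specific);
* disease-activity correlated CpGs.  DAS28 is modeled as a composite of a
  few correlated latent activity facets (as the clinical score is a
  composite of joint counts, CRP and global health); "strong" CpGs track a
  single facet on the M scale (with optional replicate CpGs per facet,
  mimicking co-methylated CpGs of one locus), "weak" CpGs couple directly
  to the score with a small slope, and a configured fraction of activity
  CpGs carry the same coupling (same sign) in the SF compartment;
* blood-vs-SF macrophage-like shifts with |delta-beta| >= 0.15 in
  expectation;
* per-sample variance heterogeneity (array-quality factors) and Gaussian
  observation noise, both on the M (log2-odds) scale.

All effects are planted on the M scale so that the Gaussian linear-model
assumptions of the moderated-t machinery hold; betas are produced by the
inverse logit and clipped to (1e-6, 1 - 1e-6).

A companion generator emits matching genomic side-data: a 15-state
chromatin segmentation with a configurable planted enrichment of truth
DMPs in the Enh state, per-trait SNP catalogs with one arthritis-like trait
placed preferentially within 1 Mbp of truth DMPs, signal peaks covering a
configured fraction of truth DMP coordinates, and promoter-capture
interaction pairs with a planted subset of other-ends over truth DMPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from .core import (
    BETA_EPS,
    MethylationMatrix,
    beta_to_m,
    m_to_beta,
    write_annotation,
    write_sample_sheet,
)
from .enrichment import ROADMAP_15_STATES, GenomicIntervalSet
from .integration import InteractionSet


class ConfigError(ValueError):
    """Raised for inconsistent cohort configurations."""


@dataclass
class CohortConfig:
    """Study-scale knobs of the synthetic cohort.

    Defaults mirror the cohort the analysis is designed for: 15 healthy
    donors, 10 + 10 patients by prognosis, four 6-monthly visits, and a
    10k-probe array at desk scale.
    """

    n_hd: int = 15
    n_gp: int = 10
    n_pp: int = 10
    visits: int = 4
    n_probes: int = 10_000
    frac_sex_chrom: float = 0.02
    frac_snp_overlap: float = 0.01

    # planted signal
    n_dmp_ua: int = 300
    frac_hyper: float = 0.90
    n_dmp_prognosis: int = 200
    n_activity_cpg: int = 40
    n_activity_facets: int = 3
    strong_reps_per_facet: int = 4
    facet_corr: float = 0.40
    activity_slope_strong: float = 1.0
    activity_slope_weak: float = 0.08
    frac_activity_negative: float = 0.6
    frac_activity_shared_sf: float = 0.75
    n_sf_dmp: int = 200
    sf_effect_logit: float = 1.5
    effect_logit_sd: float = 1.0

    # dynamics
    reversion_gp: float = 0.55
    reversion_pp: float = 0.65
    das28_visit1_range: tuple = (3.2, 7.0)
    das28_floor: float = 1.5
    das28_decay_gp: float = 0.50
    das28_decay_pp: float = 0.72
    das28_noise_sd: float = 0.15
    das28_increase_per_visit: float = 0.4
    n_das28_increase: int = 1

    # noise model
    noise_logit_sd: float = 0.25
    array_var_factors: tuple = (0.7, 1.4)
    baseline_weights: tuple = (0.4, 0.4, 0.2)

    # compartments / genome
    n_sf_patients: int = 16
    n_chrom_autosomal: int = 22
    chrom_length: int = 25_000_000

    seed: int = 0

    def __post_init__(self):
        counts = dict(n_hd=self.n_hd, n_gp=self.n_gp, n_pp=self.n_pp,
                      visits=self.visits, n_probes=self.n_probes,
                      n_dmp_ua=self.n_dmp_ua,
                      n_dmp_prognosis=self.n_dmp_prognosis,
                      n_activity_cpg=self.n_activity_cpg,
                      n_sf_dmp=self.n_sf_dmp)
        for name, v in counts.items():
            if v < 0:
                raise ConfigError(f"{name} must be >= 0 (got {v})")
        for name in ("frac_sex_chrom", "frac_snp_overlap", "frac_hyper",
                     "frac_activity_shared_sf", "frac_activity_negative",
                     "reversion_gp", "reversion_pp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1] (got {v})")
        planted = (self.n_dmp_ua + self.n_dmp_prognosis
                   + self.n_activity_cpg + self.n_sf_dmp)
        if planted > self.n_probes:
            raise ConfigError(
                f"planted sets ({planted}) exceed probe count ({self.n_probes})"
            )
        if self.n_sf_patients > self.n_gp + self.n_pp:
            raise ConfigError("n_sf_patients exceeds patient count")
        if not 0.0 <= self.facet_corr < 1.0:
            raise ConfigError("facet_corr must be in [0, 1)")
        # strong activity CpGs can never outnumber the planted activity set
        if self.n_strong_activity > self.n_activity_cpg:
            self.strong_reps_per_facet = 0

    @property
    def n_strong_activity(self) -> int:
        return self.n_activity_facets * self.strong_reps_per_facet


@dataclass
class GroundTruth:
    """Planted-signal bookkeeping emitted alongside the cohort."""

    dmp_ua: pd.DataFrame          # probe_id -> m_shift (patients vs HD)
    dmp_prognosis: pd.DataFrame   # probe_id -> m_shift (GP delta; PP = 2x)
    activity: pd.DataFrame        # probe_id -> slope, sign, shared_sf, strong
    sf_dmp: pd.DataFrame          # probe_id -> m_shift, expected delta-beta
    baseline_beta: pd.Series
    sample_var_factor: pd.Series
    das28: pd.DataFrame           # subject x visit trajectory

    @property
    def dmp_ua_ids(self):
        return list(self.dmp_ua.index)

    @property
    def dmp_prognosis_ids(self):
        return list(self.dmp_prognosis.index)

    @property
    def activity_cpg_ids(self):
        return list(self.activity.index)

    @property
    def sf_dmp_ids(self):
        return list(self.sf_dmp.index)

    @property
    def all_dmp_ids(self):
        return (self.dmp_ua_ids + self.dmp_prognosis_ids
                + self.activity_cpg_ids + self.sf_dmp_ids)


def _chrom_names(n_autosomal: int):
    return [f"chr{i}" for i in range(1, n_autosomal + 1)] + ["chrX", "chrY"]


def _make_annotation(cfg: CohortConfig, rng: np.random.Generator):
    chroms = _chrom_names(cfg.n_chrom_autosomal)
    n_sex = int(round(cfg.frac_sex_chrom * cfg.n_probes))
    n_auto = cfg.n_probes - n_sex
    assign = np.concatenate([
        rng.integers(0, cfg.n_chrom_autosomal, size=n_auto),
        rng.integers(cfg.n_chrom_autosomal, len(chroms), size=n_sex),
    ])
    pos = np.empty(cfg.n_probes, dtype=int)
    for ci in np.unique(assign):
        idx = np.flatnonzero(assign == ci)
        # unique positions so downstream segments have positive length
        draw = rng.integers(1000, cfg.chrom_length - 1000,
                            size=2 * idx.size + 16)
        uniq = np.unique(draw)[:idx.size]
        while uniq.size < idx.size:  # vanishing collision probability
            extra = rng.integers(1000, cfg.chrom_length - 1000,
                                 size=idx.size)
            uniq = np.unique(np.concatenate([uniq, extra]))[:idx.size]
        pos[idx] = np.sort(uniq)
    snp = np.zeros(cfg.n_probes, dtype=bool)
    n_snp = int(round(cfg.frac_snp_overlap * cfg.n_probes))
    snp[rng.choice(cfg.n_probes, size=n_snp, replace=False)] = True
    ann = pd.DataFrame({
        "probe_id": [f"cg{i:08d}" for i in range(cfg.n_probes)],
        "chrom": [chroms[c] for c in assign],
        "pos": pos,
        "snp_overlap": snp,
    })
    return ann


def _plant_effect_magnitudes(n: int, scale: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Effect magnitudes on the M scale, centered at ``scale``.

    Drawn N(scale, (scale/4)^2) and floored at scale/4 so every planted
    probe carries a detectable effect at the default noise level.
    """
    if scale == 0:
        return np.zeros(n)
    mags = rng.normal(scale, scale / 4.0, size=n)
    return np.maximum(np.abs(mags), scale / 4.0)


def generate_cohort(cfg: CohortConfig):
    """Generate the cohort; returns (matrices, sample_sheet, annotation, truth).

    ``matrices`` maps compartment name ("blood", "SF") to a
    :class:`~uameth.core.MethylationMatrix` holding all visits of that
    compartment.  All randomness flows from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    ann = _make_annotation(cfg, rng)
    probe_ids = ann["probe_id"].to_numpy()

    # baseline beta: three-component mixture (low / high / intermediate)
    w = np.asarray(cfg.baseline_weights, dtype=float)
    w = w / w.sum()
    comp = rng.choice(3, size=cfg.n_probes, p=w)
    baseline = np.empty(cfg.n_probes)
    baseline[comp == 0] = rng.beta(2, 20, size=int(np.sum(comp == 0)))
    baseline[comp == 1] = rng.beta(20, 2, size=int(np.sum(comp == 1)))
    baseline[comp == 2] = rng.beta(5, 5, size=int(np.sum(comp == 2)))
    baseline = np.clip(baseline, BETA_EPS, 1 - BETA_EPS)
    m_base = beta_to_m(baseline)

    # eligible probes for planting: autosomal, non-SNP
    eligible = np.flatnonzero(
        (~ann["snp_overlap"].to_numpy())
        & (~ann["chrom"].isin(["chrX", "chrY"]).to_numpy())
    )
    # SF DMPs need mid-range baselines so |delta-beta| >= 0.15 is achievable
    sf_eligible = eligible[(baseline[eligible] > 0.2)
                           & (baseline[eligible] < 0.8)]
    n_planted = (cfg.n_dmp_ua + cfg.n_dmp_prognosis + cfg.n_activity_cpg
                 + cfg.n_sf_dmp)
    if n_planted > eligible.size:
        raise ConfigError("not enough eligible probes for the planted sets")
    if cfg.n_sf_dmp > sf_eligible.size:
        raise ConfigError("not enough mid-range probes for SF DMPs")

    sf_idx = rng.choice(sf_eligible, size=cfg.n_sf_dmp, replace=False)
    remaining = np.setdiff1d(eligible, sf_idx)
    picks = rng.choice(remaining,
                       size=cfg.n_dmp_ua + cfg.n_dmp_prognosis
                       + cfg.n_activity_cpg, replace=False)
    ua_idx = picks[:cfg.n_dmp_ua]
    prog_idx = picks[cfg.n_dmp_ua:cfg.n_dmp_ua + cfg.n_dmp_prognosis]
    act_idx = picks[cfg.n_dmp_ua + cfg.n_dmp_prognosis:]

    # UA effects: hyper with probability frac_hyper
    ua_sign = np.where(rng.random(cfg.n_dmp_ua) < cfg.frac_hyper, 1.0, -1.0)
    ua_shift = ua_sign * _plant_effect_magnitudes(
        cfg.n_dmp_ua, cfg.effect_logit_sd, rng)

    prog_sign = np.where(rng.random(cfg.n_dmp_prognosis) < cfg.frac_hyper,
                         1.0, -1.0)
    prog_shift = prog_sign * _plant_effect_magnitudes(
        cfg.n_dmp_prognosis, cfg.effect_logit_sd, rng)

    # Activity CpGs.  DAS28 is a composite score; patients carry three
    # correlated latent activity facets whose normalized sum defines the
    # score.  "Strong" CpGs track a single facet (with replicate CpGs per
    # facet, as co-methylated CpGs of one locus do), which keeps their
    # pairwise correlation below the |r| < 0.5 panel constraint while each
    # still correlates strongly with the composite.  "Weak" CpGs couple
    # directly to the score with a small slope.
    n_strong = cfg.n_strong_activity
    strong_flag = np.arange(cfg.n_activity_cpg) < n_strong
    facet_of = np.full(cfg.n_activity_cpg, -1)
    if n_strong:
        facet_of[:n_strong] = np.repeat(np.arange(cfg.n_activity_facets),
                                        cfg.strong_reps_per_facet)
    slopes = np.where(strong_flag, cfg.activity_slope_strong,
                      cfg.activity_slope_weak)
    act_sign = np.where(
        rng.random(cfg.n_activity_cpg) < cfg.frac_activity_negative,
        -1.0, 1.0)
    slopes = slopes * act_sign
    # SF sharing is a stratified deterministic fraction (per facet for the
    # strong CpGs) so the planted fraction is exact, not binomial
    shared = np.zeros(cfg.n_activity_cpg, dtype=bool)
    for block in ([np.flatnonzero(facet_of == f)
                   for f in range(cfg.n_activity_facets)]
                  + [np.flatnonzero(~strong_flag)]):
        if len(block) == 0:
            continue
        k = int(round(cfg.frac_activity_shared_sf * len(block)))
        shared[rng.permutation(block)[:k]] = True
    # loading of each facet on the composite: corr(f_i, z) for equicorrelated
    # facets with pairwise correlation facet_corr
    facet_loading = np.sqrt((1.0 + 2.0 * cfg.facet_corr) / 3.0)

    # SF shifts point toward beta = 0.5 so |delta-beta| stays >= 0.15
    sf_sign = np.where(baseline[sf_idx] <= 0.5, 1.0, -1.0)
    sf_shift = sf_sign * (cfg.sf_effect_logit
                          * np.maximum(rng.normal(1.0, 0.1, cfg.n_sf_dmp),
                                       0.7))
    sf_expected_db = m_to_beta(m_base[sf_idx] + sf_shift) - baseline[sf_idx]

    # subjects and DAS28 trajectories
    subjects = ([f"HD{i + 1:02d}" for i in range(cfg.n_hd)]
                + [f"GP{i + 1:02d}" for i in range(cfg.n_gp)]
                + [f"PP{i + 1:02d}" for i in range(cfg.n_pp)])
    groups = (["HD"] * cfg.n_hd + ["GP"] * cfg.n_gp + ["PP"] * cfg.n_pp)
    das28 = {}
    z_traj = {}
    facets_of_subj = {}
    increasing = {f"PP{cfg.n_pp - i:02d}" for i in range(cfg.n_das28_increase)
                  if cfg.n_pp - i >= 1}
    lo, hi = cfg.das28_visit1_range

    def _z_from_das(d):
        # inverse of the composite -> uniform DAS28 mapping at visit 1
        u = np.clip((d - lo) / (hi - lo), 1e-4, 1 - 1e-4)
        return float(_norm.ppf(u))

    for subj, grp in zip(subjects, groups):
        if grp == "HD":
            das28[subj] = [np.nan] * cfg.visits
            continue
        # standard-normal activity composite; the uniform visit-1 DAS28 is
        # its probability transform onto [lo, hi]
        z1 = rng.normal()
        d1 = lo + (hi - lo) * float(_norm.cdf(z1))
        # facet-specific components orthogonal to the composite (sum to 0)
        g = rng.normal(0.0, np.sqrt(max(1.0 - cfg.facet_corr, 1e-12)),
                       size=cfg.n_activity_facets)
        facets_of_subj[subj] = g - g.mean()
        traj = [d1]
        decay = cfg.das28_decay_gp if grp == "GP" else cfg.das28_decay_pp
        for v in range(1, cfg.visits):
            if subj in increasing:
                nxt = traj[-1] + cfg.das28_increase_per_visit
            else:
                nxt = (cfg.das28_floor
                       + (traj[-1] - cfg.das28_floor) * decay)
            traj.append(max(0.3, nxt + rng.normal(0, cfg.das28_noise_sd)))
        das28[subj] = traj
        z_traj[subj] = [_z_from_das(d) for d in traj]
    das28_df = pd.DataFrame(das28, index=range(1, cfg.visits + 1)).T
    das28_df.columns = [f"visit{v}" for v in range(1, cfg.visits + 1)]
    das_center = 0.5 * (lo + hi)

    # enumerate samples
    sf_subjects = ([f"GP{i + 1:02d}" for i in range(cfg.n_sf_patients // 2)]
                   + [f"PP{i + 1:02d}"
                      for i in range(cfg.n_sf_patients
                                     - cfg.n_sf_patients // 2)])
    records = []
    for subj, grp in zip(subjects, groups):
        visit_list = [1] if grp == "HD" else list(range(1, cfg.visits + 1))
        for v in visit_list:
            records.append({
                "sample_id": f"{subj}_bl_v{v}", "subject_id": subj,
                "group": grp, "compartment": "blood", "visit": v,
                "das28": das28[subj][v - 1],
                "treated_dmard": grp == "PP" and subj not in increasing,
            })
        if subj in sf_subjects:
            records.append({
                "sample_id": f"{subj}_sf_v1", "subject_id": subj,
                "group": grp, "compartment": "SF", "visit": 1,
                "das28": das28[subj][0],
                "treated_dmard": grp == "PP" and subj not in increasing,
            })
    sheet = pd.DataFrame(records)

    var_lo, var_hi = cfg.array_var_factors
    var_factors = pd.Series(
        rng.uniform(var_lo, var_hi, size=len(sheet)),
        index=sheet["sample_id"], name="var_factor")

    # assemble M-value columns
    cols = {}
    for rec, vf in zip(records, var_factors):
        grp, v, comp = rec["group"], rec["visit"], rec["compartment"]
        m = m_base.copy()
        if grp in ("GP", "PP"):
            decay = cfg.reversion_gp if grp == "GP" else cfg.reversion_pp
            factor = decay ** (v - 1)
            m[ua_idx] += ua_shift * factor
            mult = 1.0 if grp == "GP" else 2.0
            m[prog_idx] += prog_shift * mult * factor
        das = rec["das28"]
        if das is not None and np.isfinite(das) and cfg.n_activity_cpg:
            subj = rec["subject_id"]
            z_v = z_traj[subj][v - 1]
            o = facets_of_subj[subj]
            if comp == "blood":
                if n_strong:
                    facet_val = (facet_loading * z_v
                                 + o[facet_of[:n_strong]])
                    m[act_idx[:n_strong]] += slopes[:n_strong] * facet_val
                weak = ~strong_flag
                m[act_idx[weak]] += slopes[weak] * (das - das_center)
            else:
                # at the inflamed site the global activity drive dominates
                # the facet-specific variation: shared CpGs couple to the
                # composite directly
                st_sh = strong_flag & shared
                m[act_idx[st_sh]] += slopes[st_sh] * z_v
                wk_sh = ~strong_flag & shared
                m[act_idx[wk_sh]] += slopes[wk_sh] * (das - das_center)
        if comp == "SF":
            m[sf_idx] += sf_shift
        if cfg.noise_logit_sd > 0:
            m = m + rng.normal(0.0, cfg.noise_logit_sd * np.sqrt(vf),
                               size=cfg.n_probes)
        cols[rec["sample_id"]] = m

    beta_all = pd.DataFrame(
        {sid: np.clip(m_to_beta(mm), BETA_EPS, 1 - BETA_EPS)
         for sid, mm in cols.items()},
        index=pd.Index(probe_ids, name="probe_id"))

    matrices = {}
    for comp in ("blood", "SF"):
        sids = sheet.loc[sheet["compartment"] == comp, "sample_id"]
        if len(sids):
            matrices[comp] = MethylationMatrix(beta_all[list(sids)])

    truth = GroundTruth(
        dmp_ua=pd.DataFrame(
            {"m_shift": ua_shift,
             "direction": np.where(ua_shift > 0, "hyper", "hypo")},
            index=pd.Index(probe_ids[ua_idx], name="probe_id")),
        dmp_prognosis=pd.DataFrame(
            {"m_shift": prog_shift,
             "direction": np.where(prog_shift > 0, "hyper", "hypo")},
            index=pd.Index(probe_ids[prog_idx], name="probe_id")),
        activity=pd.DataFrame(
            {"slope": slopes, "sign": np.where(slopes > 0, "+", "-"),
             "shared_sf": shared, "strong": strong_flag,
             "facet": facet_of},
            index=pd.Index(probe_ids[act_idx], name="probe_id")),
        sf_dmp=pd.DataFrame(
            {"m_shift": sf_shift, "expected_delta_beta": sf_expected_db},
            index=pd.Index(probe_ids[sf_idx], name="probe_id")),
        baseline_beta=pd.Series(baseline,
                                index=pd.Index(probe_ids, name="probe_id"),
                                name="baseline_beta"),
        sample_var_factor=var_factors,
        das28=das28_df,
    )
    return matrices, sheet, ann, truth


def predictor_recovery_config(seed: int,
                              shared_sf: float = 0.75) -> CohortConfig:
    """Cohort design for the predictor dimensionality-recovery study.

    Plants exactly three strong activity CpGs, one per latent facet, in a
    large single-visit cohort (200 + 200 patients).  The facet correlation
    and slope put the true CpG-DAS28 Spearman correlation near 0.76 —
    comfortably above the 0.7 retention screen yet with cross-CpG
    correlations near 0.41, below the 0.5 collinearity bound.  This is the
    only regime where both of the method's thresholds can hold
    simultaneously: three CpGs each correlating above ~0.82 with a common
    score must pairwise correlate above 0.5.  The enlarged sample keeps
    the sampling noise of both correlations inside the two margins (about
    2 standard errors each).
    """
    return CohortConfig(
        seed=seed, n_gp=200, n_pp=200, n_sf_patients=40, visits=1,
        n_activity_cpg=20, n_activity_facets=3, strong_reps_per_facet=1,
        facet_corr=0.42, activity_slope_strong=2.0,
        frac_activity_shared_sf=shared_sf,
    )


# ---------------------------------------------------------------------------
# Genomic side-data
# ---------------------------------------------------------------------------

@dataclass
class ContextConfig:
    """Knobs of the synthetic genomic context."""

    enh_odds_ratio: float = 4.0
    enh_background_frac: float = 0.10
    n_snps_per_trait: int = 150
    frac_snp_near_dmp: float = 0.6
    arthritis_trait: str = "rheumatoid_arthritis_like"
    control_traits: tuple = ("osteoarthritis_like", "schizophrenia_like",
                             "myocardial_infarction_like", "alzheimers_like")
    snp_window_bp: int = 1_000_000
    peak_frac_dmp: float = 0.6
    peak_frac_background: float = 0.05
    peak_halfwidth: int = 50
    n_genes: int = 100
    n_interactions: int = 150
    n_interactions_dmp: int = 50
    n_interactions_no_tss: int = 5
    fragment_halfwidth: int = 2000

    def __post_init__(self):
        if self.enh_odds_ratio < 0:
            raise ConfigError("enh_odds_ratio must be >= 0")
        for name in ("frac_snp_near_dmp", "peak_frac_dmp",
                     "peak_frac_background", "enh_background_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")


# background occupancy of the 15 chromatin states (Quies-heavy, Enh filled
# in from enh_background_frac)
_STATE_BG_WEIGHTS = {
    "TssA": 0.03, "TssAFlnk": 0.02, "TxFlnk": 0.02, "Tx": 0.10, "TxWk": 0.12,
    "EnhG": 0.03, "ZNF/Rpts": 0.01, "Het": 0.05, "TssBiv": 0.01,
    "BivFlnk": 0.01, "EnhBiv": 0.02, "ReprPC": 0.04, "ReprPCWk": 0.06,
    "Quies": 0.38,
}


def generate_genomic_context(cohort_cfg: CohortConfig,
                             annotation: pd.DataFrame,
                             truth: GroundTruth,
                             ctx: ContextConfig | None = None,
                             seed: int | None = None):
    """Generate (state_map, snp_catalog, peak_set, interactions, tss_set).

    The truth DMP set used for planting is the UA DMP set.  Enrichment of
    truth probes in the "Enh" state is planted at ``ctx.enh_odds_ratio``
    against a background occupancy of ``ctx.enh_background_frac``.
    """
    ctx = ctx or ContextConfig()
    rng = np.random.default_rng(cohort_cfg.seed + 1 if seed is None else seed)
    ann = annotation.set_index("probe_id")
    truth_ids = pd.Index(truth.dmp_ua_ids)
    is_truth = ann.index.isin(truth_ids)

    # --- chromatin states: per-probe labels, then midpoint-bounded segments
    p_bg = ctx.enh_background_frac
    odds_fg = ctx.enh_odds_ratio * p_bg / (1 - p_bg)
    p_fg = odds_fg / (1 + odds_fg) if np.isfinite(odds_fg) else 1.0
    other_states = [s for s in ROADMAP_15_STATES if s != "Enh"]
    other_w = np.array([_STATE_BG_WEIGHTS[s] for s in other_states])
    other_w = other_w / other_w.sum()
    labels = np.empty(len(ann), dtype=object)
    for i, t in enumerate(is_truth):
        p_enh = p_fg if t else p_bg
        if rng.random() < p_enh:
            labels[i] = "Enh"
        else:
            labels[i] = other_states[rng.choice(len(other_states), p=other_w)]

    seg_rows = []
    pos0 = ann["pos"].to_numpy() - 1
    for chrom in ann["chrom"].unique():
        mask = (ann["chrom"] == chrom).to_numpy()
        order = np.argsort(pos0[mask], kind="mergesort")
        cpos = pos0[mask][order]
        clab = labels[mask][order]
        mids = (cpos[:-1] + cpos[1:]) // 2 + 1
        starts = np.concatenate([[0], mids])
        ends = np.concatenate([mids, [cohort_cfg.chrom_length]])
        for s, e, lab in zip(starts, ends, clab):
            seg_rows.append({"chrom": chrom, "start": int(s), "end": int(e),
                             "label": lab})
    state_map = GenomicIntervalSet(pd.DataFrame(seg_rows))

    # --- SNP catalogs
    chroms = list(ann["chrom"].unique())
    truth_pos = ann.loc[truth_ids, ["chrom", "pos"]] if len(truth_ids) \
        else pd.DataFrame(columns=["chrom", "pos"])
    half = ctx.snp_window_bp // 2
    snp_rows = []
    for trait in [ctx.arthritis_trait, *ctx.control_traits]:
        near_frac = ctx.frac_snp_near_dmp if trait == ctx.arthritis_trait \
            else 0.0
        n_near = int(round(near_frac * ctx.n_snps_per_trait)) \
            if len(truth_pos) else 0
        for k in range(ctx.n_snps_per_trait):
            if k < n_near:
                row = truth_pos.iloc[rng.integers(0, len(truth_pos))]
                offset = rng.integers(-(half - 1000), half - 1000)
                chrom = row["chrom"]
                pos = int(np.clip(row["pos"] + offset, 1,
                                  cohort_cfg.chrom_length))
            else:
                chrom = chroms[rng.integers(0, len(chroms))]
                pos = int(rng.integers(1, cohort_cfg.chrom_length))
            snp_rows.append({"trait": trait, "snp_id": f"rs{trait[:2]}{k:05d}",
                             "chrom": chrom, "pos": pos})
    snp_catalog = pd.DataFrame(snp_rows)

    # --- peaks
    peak_rows = []
    n_cover = int(round(ctx.peak_frac_dmp * len(truth_pos)))
    cover_ids = rng.choice(len(truth_pos), size=n_cover, replace=False) \
        if n_cover else []
    for i in cover_ids:
        row = truth_pos.iloc[i]
        c = int(row["pos"]) - 1
        peak_rows.append({"chrom": row["chrom"],
                          "start": max(0, c - ctx.peak_halfwidth),
                          "end": c + ctx.peak_halfwidth,
                          "label": "peak"})
    bg_ids = ann.index[~is_truth]
    n_bg = int(round(ctx.peak_frac_background * len(bg_ids)))
    for pid in rng.choice(bg_ids, size=n_bg, replace=False):
        row = ann.loc[pid]
        c = int(row["pos"]) - 1
        peak_rows.append({"chrom": row["chrom"],
                          "start": max(0, c - ctx.peak_halfwidth),
                          "end": c + ctx.peak_halfwidth,
                          "label": "peak"})
    peak_set = GenomicIntervalSet(pd.DataFrame(
        peak_rows, columns=["chrom", "start", "end", "label"]))

    # --- genes / TSS / interactions
    tss_rows = []
    genes = []
    for g in range(ctx.n_genes):
        chrom = chroms[rng.integers(0, len(chroms))]
        tss = int(rng.integers(100_000, cohort_cfg.chrom_length - 100_000))
        name = f"GENE{g + 1:04d}"
        genes.append((name, chrom, tss))
        tss_rows.append({"chrom": chrom, "start": tss, "end": tss + 1000,
                         "label": name})
    tss_set = GenomicIntervalSet(pd.DataFrame(
        tss_rows, columns=["chrom", "start", "end", "label"]))

    fw = ctx.fragment_halfwidth
    inter_rows = []
    n_dmp_inter = min(ctx.n_interactions_dmp, ctx.n_interactions,
                      len(truth_pos))
    # pick DMP targets whose fragment would contain no other planted probe,
    # so the recovered pair count equals the planted count exactly
    all_planted = ann.loc[ann.index.isin(truth.all_dmp_ids),
                          ["chrom", "pos"]]
    chosen = []
    for i in rng.permutation(len(truth_pos)):
        if len(chosen) >= n_dmp_inter:
            break
        row = truth_pos.iloc[i]
        near = all_planted[
            (all_planted["chrom"] == row["chrom"])
            & ((all_planted["pos"] - row["pos"]).abs() < 2 * fw + 10)
        ]
        if len(near) == 1:  # only itself
            chosen.append(i)
    if len(chosen) < n_dmp_inter:
        warnings.warn("could not isolate enough DMP fragments; planted "
                      f"{len(chosen)} DMP interactions", stacklevel=2)
    for i in chosen:
        row = truth_pos.iloc[i]
        gname, gchrom, gtss = genes[rng.integers(0, len(genes))]
        c = int(row["pos"]) - 1
        inter_rows.append({
            "chrom1": gchrom, "start1": gtss - 4000, "end1": gtss + 6000,
            "chrom2": row["chrom"], "start2": max(0, c - fw),
            "end2": c + fw, "gene": gname,
            "score": float(np.round(rng.uniform(5, 15), 3)),
        })
    n_rand = ctx.n_interactions - len(inter_rows)
    for _ in range(max(0, n_rand)):
        gname, gchrom, gtss = genes[rng.integers(0, len(genes))]
        oc = chroms[rng.integers(0, len(chroms))]
        # keep random other-ends away from planted probes
        for _attempt in range(20):
            opos = int(rng.integers(fw, cohort_cfg.chrom_length - fw))
            near = all_planted[(all_planted["chrom"] == oc)
                               & ((all_planted["pos"] - opos).abs()
                                  < fw + 10)]
            if near.empty:
                break
        inter_rows.append({
            "chrom1": gchrom, "start1": gtss - 4000, "end1": gtss + 6000,
            "chrom2": oc, "start2": opos - fw, "end2": opos + fw,
            "gene": gname,
            "score": float(np.round(rng.uniform(5, 15), 3)),
        })
    for _ in range(ctx.n_interactions_no_tss):
        oc = chroms[rng.integers(0, len(chroms))]
        a = int(rng.integers(fw, cohort_cfg.chrom_length - fw))
        b = int(rng.integers(fw, cohort_cfg.chrom_length - fw))
        tss_here = tss_set.records[tss_set.records["chrom"] == oc]
        if (((tss_here["start"] < a + fw) & (tss_here["end"] > a - fw)).any()
                or ((tss_here["start"] < b + fw)
                    & (tss_here["end"] > b - fw)).any()):
            continue
        inter_rows.append({
            "chrom1": oc, "start1": a - fw, "end1": a + fw,
            "chrom2": oc, "start2": b - fw, "end2": b + fw,
            "gene": ".", "score": float(np.round(rng.uniform(5, 15), 3)),
        })
    interactions = InteractionSet(pd.DataFrame(
        inter_rows, columns=["chrom1", "start1", "end1", "chrom2", "start2",
                             "end2", "gene", "score"]))
    planted_pairs = pd.DataFrame(
        [{"probe_id": truth_pos.index[i], "interaction_id": j}
         for j, i in enumerate(chosen)])
    return state_map, snp_catalog, peak_set, interactions, tss_set, \
        planted_pairs


# ---------------------------------------------------------------------------
# Disk output
# ---------------------------------------------------------------------------

def write_cohort(outdir, matrices, sheet, annotation, truth,
                 context=None) -> None:
    """Write the cohort (and optional genomic context) as TSV/BED/BEDPE."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for comp, mat in matrices.items():
        mat.to_tsv(outdir / f"beta_{comp.lower()}.tsv")
    write_sample_sheet(sheet, outdir / "samples.tsv")
    write_annotation(annotation, outdir / "annotation.tsv")
    truth.dmp_ua.to_csv(outdir / "truth_dmp_ua.tsv", sep="\t")
    truth.dmp_prognosis.to_csv(outdir / "truth_dmp_prognosis.tsv", sep="\t")
    truth.activity.to_csv(outdir / "truth_activity.tsv", sep="\t")
    truth.sf_dmp.to_csv(outdir / "truth_sf_dmp.tsv", sep="\t")
    truth.baseline_beta.to_csv(outdir / "truth_baseline.tsv", sep="\t")
    truth.sample_var_factor.to_csv(outdir / "truth_var_factors.tsv", sep="\t")
    truth.das28.to_csv(outdir / "truth_das28.tsv", sep="\t")
    if context is not None:
        state_map, snps, peaks, interactions, tss, planted_pairs = context
        state_map.to_bed(outdir / "states.bed")
        snps.to_csv(outdir / "snps.tsv", sep="\t", index=False)
        peaks.to_bed(outdir / "peaks.bed")
        interactions.to_bedpe(outdir / "interactions.bedpe")
        tss.to_bed(outdir / "tss.bed")
        planted_pairs.to_csv(outdir / "truth_interaction_pairs.tsv",
                             sep="\t", index=False)
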