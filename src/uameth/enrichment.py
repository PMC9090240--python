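"""Fisher's-exact enrichment of DMP sets in genomic context.

Foreground DMPs are compared against the full probe annotation (the array
background) for membership in chromatin-state segments, proximity to GWAS
trait SNPs, and overlap with signal peaks in offset windows around the
probe coordinate.  All interval arithmetic is 0-based half-open; probe
points from the 1-based annotation map to [pos - 1, pos).

Two-sided Fisher p-values follow the probability-mass rule (sum of tables
with hypergeometric probability <= that observed).  Zero-cell odds ratios
are reported as the +inf / 0 / NaN sentinels of the sample odds ratio
(a*d)/(b*c) unless the Haldane +0.5 correction is requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

ROADMAP_15_STATES = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)

UNSEGMENTED = "Unsegmented"


@dataclass
class GenomicIntervalSet:
    """Labeled genomic intervals, 0-based half-open."""

    records: pd.DataFrame  # columns chrom, start, end, label

    def __post_init__(self):
        df = self.records
        required = ["chrom", "start", "end", "label"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"interval set missing columns: {missing}")
        if ((df["end"] - df["start"]) <= 0).any():
            bad = df.index[(df["end"] - df["start"]) <= 0][0]
            raise ValueError(f"interval row {bad}: start >= end")
        self.records = df.reset_index(drop=True)

    def __len__(self):
        return len(self.records)

    @classmethod
    def from_bed(cls, path) -> "GenomicIntervalSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2, 3],
                         names=["chrom", "start", "end", "label"])
        return cls(df)

    def to_bed(self, path) -> None:
        self.records[["chrom", "start", "end", "label"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     haldane: bool = False) -> tuple[float, float]:
    """Sample odds ratio and two-sided Fisher exact p for a 2x2 table.

    The table is [[a, b], [c, d]].  OR = (a*d)/(b*c); a zero denominator
    with nonzero numerator yields +inf, a zero numerator with nonzero
    denominator yields 0, both zero yields NaN.  A zero margin makes the
    table degenerate: p = 1.  With ``haldane`` the +0.5 correction is added
    to every cell of the OR (p is unaffected).
    """
    cells = (a, b, c, d)
    if any(v < 0 or v != int(v) for v in cells):
        raise ValueError("cells must be nonnegative integers")
    a, b, c, d = (int(v) for v in cells)
    if haldane:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        num, den = a * d, b * c
        if den > 0:
            odds = num / den
        else:
            odds = np.inf if num > 0 else np.nan
    if min(a + b, c + d, a + c, b + d) == 0:
        return odds, 1.0
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(min(p, 1.0))


def _probe_positions(annotation: pd.DataFrame) -> pd.DataFrame:
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns \
        else annotation
    return ann[["chrom", "pos"]]


def assign_states(annotation: pd.DataFrame,
                  state_map: GenomicIntervalSet) -> pd.Series:
    """Map each probe to the state whose interval contains its coordinate.

    The segmentation is assumed to be a partition (non-overlapping); probes
    outside every interval get the ``Unsegmented`` label.
    """
    pos = _probe_positions(annotation)
    out = pd.Series(UNSEGMENTED, index=pos.index, dtype=object)
    recs = state_map.records
    for chrom, sub in recs.groupby("chrom", sort=False):
        mask = pos["chrom"] == chrom
        if not mask.any():
            continue
        sub = sub.sort_values("start", kind="mergesort")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        labels = sub["label"].to_numpy()
        points = pos.loc[mask, "pos"].to_numpy() - 1  # 0-based point
        idx = np.searchsorted(starts, points, side="right") - 1
        hit = (idx >= 0) & (points < ends[np.clip(idx, 0, None)])
        assigned = np.where(hit, labels[np.clip(idx, 0, None)], UNSEGMENTED)
        out.loc[mask] = assigned
    return out


def _enrichment_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["label", "a", "b", "c", "d",
                                     "odds_ratio", "p"])
    df["fdr"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


def state_enrichment(dmp_ids, state_map: GenomicIntervalSet,
                     annotation: pd.DataFrame,
                     haldane: bool = False) -> pd.DataFrame:
    """Per-state Fisher enrichment of the foreground against the array.

    For each state: a = foreground probes in the state, b = foreground
    elsewhere, c = background (non-foreground annotated) probes in the
    state, d = the rest.  BH adjustment across states.
    """
    states = assign_states(annotation, state_map)
    fg = pd.Index(dmp_ids).unique()
    unknown = fg.difference(states.index)
    if len(unknown):
        raise ValueError(f"{len(unknown)} foreground probes not in annotation")
    if len(fg) >= len(states):
        raise ValueError("foreground must be a proper subset of the background")
    is_fg = states.index.isin(fg)
    rows = []
    for label in sorted(states.unique()):
        in_state = (states == label).to_numpy()
        a = int(np.sum(in_state & is_fg))
        b = int(np.sum(~in_state & is_fg))
        c = int(np.sum(in_state & ~is_fg))
        d = int(np.sum(~in_state & ~is_fg))
        odds, p = fisher_exact_2x2(a, b, c, d, haldane=haldane)
        rows.append({"label": label, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p": p})
    return _enrichment_frame(rows)


def snp_proximity_enrichment(dmp_ids, snp_catalog: pd.DataFrame,
                             annotation: pd.DataFrame,
                             window_bp: int = 1_000_000,
                             centered: bool = True,
                             haldane: bool = False) -> pd.DataFrame:
    """Per-trait Fisher enrichment of trait-SNP proximity.

    A probe is "trait-proximal" when at least one SNP of the trait lies
    within the window around the probe coordinate.  With ``centered`` the
    window totals ``window_bp`` (+-window/2 around the probe, the default
    reading of "a 1 Mbp window around the coordinate"); otherwise the full
    ``window_bp`` is applied on each side.
    """
    half = window_bp // 2 if centered else window_bp
    pos = _probe_positions(annotation)
    fg = pd.Index(dmp_ids).unique()
    unknown = fg.difference(pos.index)
    if len(unknown):
        raise ValueError(f"{len(unknown)} foreground probes not in annotation")
    is_fg = pos.index.isin(fg)
    rows = []
    for trait, snps in snp_catalog.groupby("trait", sort=True):
        if snps.empty:
            warnings.warn(f"trait {trait!r} has no SNPs; skipped", stacklevel=2)
            continue
        proximal = np.zeros(len(pos), dtype=bool)
        for chrom, sub in snps.groupby("chrom", sort=False):
            mask = (pos["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            spos = np.sort(sub["pos"].to_numpy())
            p_here = pos.loc[pos["chrom"] == chrom, "pos"].to_numpy()
            lo = np.searchsorted(spos, p_here - half, side="left")
            hi = np.searchsorted(spos, p_here + half, side="right")
            proximal[mask] = hi > lo
        a = int(np.sum(proximal & is_fg))
        b = int(np.sum(~proximal & is_fg))
        c = int(np.sum(proximal & ~is_fg))
        d = int(np.sum(~proximal & ~is_fg))
        odds, p = fisher_exact_2x2(a, b, c, d, haldane=haldane)
        rows.append({"label": trait, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p": p})
    return _enrichment_frame(rows)


def signal_window_enrichment(dmp_ids, peak_set: GenomicIntervalSet,
                             annotation: pd.DataFrame,
                             window_bp: int = 100,
                             flank_bp: int = 1000,
                             haldane: bool = False) -> pd.DataFrame:
    """Offset-binned Fisher enrichment of peak overlap around probes.

    The flank on each side of the probe is divided into ``window_bp`` bins;
    bin k spans [probe + k*window, probe + (k+1)*window) for
    k in [-flank/window, flank/window).  A probe "hits" a bin when the bin
    overlaps at least one peak interval.  The bin starting at offset 0 (the
    probe coordinate itself) is the headline statistic.
    """
    if flank_bp % window_bp != 0:
        raise ValueError("flank_bp must be a multiple of window_bp")
    pos = _probe_positions(annotation)
    fg = pd.Index(dmp_ids).unique()
    unknown = fg.difference(pos.index)
    if len(unknown):
        raise ValueError(f"{len(unknown)} foreground probes not in annotation")
    is_fg = pos.index.isin(fg)
    n_bins_side = flank_bp // window_bp
    offsets = [k * window_bp for k in range(-n_bins_side, n_bins_side)]

    # per chromosome: sorted peak starts/ends for interval-overlap queries
    peaks_by_chrom = {}
    for chrom, sub in peak_set.records.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="mergesort")
        peaks_by_chrom[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())

    rows = []
    for off in offsets:
        hit = np.zeros(len(pos), dtype=bool)
        for chrom, (starts, ends) in peaks_by_chrom.items():
            mask = (pos["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            point0 = pos.loc[pos["chrom"] == chrom, "pos"].to_numpy() - 1
            bin_start = point0 + off
            bin_end = bin_start + window_bp
            # overlap iff some peak has start < bin_end and end > bin_start
            idx = np.searchsorted(starts, bin_end, side="left") - 1
            ok = idx >= 0
            # nearest peak starting before bin_end; need its end > bin_start.
            # peaks may not be sorted by end; scan a little by using cummax.
            cummax_end = np.maximum.accumulate(ends)
            ok &= cummax_end[np.clip(idx, 0, None)] > bin_start
            hit[mask] = ok
        a = int(np.sum(hit & is_fg))
        b = int(np.sum(~hit & is_fg))
        c = int(np.sum(hit & ~is_fg))
        d = int(np.sum(~hit & ~is_fg))
        odds, p = fisher_exact_2x2(a, b, c, d, haldane=haldane)
        rows.append({"label": off, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p": p})
    out = _enrichment_frame(rows)
    return out.rename(columns={"label": "offset"})


def overlap_sets(top_ids_a, top_ids_b) -> tuple[int, float]:
    """Intersection size and its percentage of the combined total.

    The denominator is |a| + |b| (combined total of both lists), so two
    identical k-lists give 50%.
    """
    a = set(top_ids_a)
    b = set(top_ids_b)
    inter = len(a & b)
    total = len(a) + len(b)
    pct = 100.0 * inter / total if total else 0.0
    return inter, pct


def read_snp_catalog(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["trait", "snp_id", "chrom", "pos"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"SNP catalog missing columns: {missing}")
    if df.duplicated(["trait", "snp_id"]).any():
        raise ValueError("SNP catalog has duplicate (trait, snp_id) entries")
    return df


def write_snp_catalog(df: pd.DataFrame, path) -> None:
    df[["trait", "snp_id", "chrom", "pos"]].to_csv(path, sep="\t", index=False)
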