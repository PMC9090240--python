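"""Promoter-capture interaction overlap: nominate DMP-gene pairs.

Promoter-capture Hi-C gives pairs of restriction fragments in spatial
contact where one end (the bait) is anchored at a gene promoter.  A DMP
falling inside the non-bait ("other end") fragment of such a pair is
nominated as potentially regulating the baited gene.  Interactions whose
bait end overlaps no TSS are skipped (and counted); DMPs inside the bait
fragment itself are promoter-proximal rather than distal partners and are
excluded by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .enrichment import GenomicIntervalSet

logger = logging.getLogger(__name__)

INTERACTION_COLUMNS = ["chrom1", "start1", "end1",
                       "chrom2", "start2", "end2", "gene", "score"]


@dataclass
class InteractionSet:
    """BEDPE-like promoter-capture interaction pairs (0-based half-open)."""

    records: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in INTERACTION_COLUMNS
                   if c not in self.records.columns]
        if missing:
            raise ValueError(f"interaction set missing columns: {missing}")
        self.records = self.records.reset_index(drop=True)

    def __len__(self):
        return len(self.records)

    @classmethod
    def from_bedpe(cls, path) -> "InteractionSet":
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=INTERACTION_COLUMNS, header=None)
        return cls(df)

    def to_bedpe(self, path) -> None:
        self.records[INTERACTION_COLUMNS].to_csv(path, sep="\t",
                                                 header=False, index=False)


def _interval_overlaps_any(chrom, start, end, intervals: pd.DataFrame) -> bool:
    sub = intervals[intervals["chrom"] == chrom]
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())


def overlap_dmps_interactions(
    dmp_ids,
    annotation: pd.DataFrame,
    interactions: InteractionSet,
    tss: GenomicIntervalSet,
    include_bait_dmps: bool = False,
) -> pd.DataFrame:
    """Nominate (DMP, gene) pairs from promoter-capture interactions.

    For each interaction with a bait end on a TSS, every DMP whose point
    coordinate falls inside the non-bait fragment yields one pair; the gene
    is taken from the bait TSS annotation.  Returns a DataFrame with
    probe_id, gene, interaction id and the distance from the probe to the
    bait fragment midpoint.
    """
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns \
        else annotation
    dmp_ids = pd.Index(dmp_ids).unique()
    unknown = dmp_ids.difference(ann.index)
    if len(unknown):
        raise ValueError(f"{len(unknown)} DMPs missing from annotation")
    points = ann.loc[dmp_ids, ["chrom", "pos"]].copy()
    points["pt"] = points["pos"] - 1  # 0-based point

    tss_df = tss.records
    rows = []
    skipped = 0
    for idx, rec in interactions.records.iterrows():
        end1_is_bait = _interval_overlaps_any(
            rec["chrom1"], rec["start1"], rec["end1"], tss_df)
        end2_is_bait = _interval_overlaps_any(
            rec["chrom2"], rec["start2"], rec["end2"], tss_df)
        if not end1_is_bait and not end2_is_bait:
            skipped += 1
            continue
        ends = []
        if end1_is_bait:
            ends.append((("chrom2", "start2", "end2"),
                         ("chrom1", "start1", "end1")))
        if end2_is_bait and not end1_is_bait:
            ends.append((("chrom1", "start1", "end1"),
                         ("chrom2", "start2", "end2")))
        for (oc, os_, oe), (bc, bs, be) in ends:
            sub = points[(points["chrom"] == rec[oc])
                         & (points["pt"] >= rec[os_])
                         & (points["pt"] < rec[oe])]
            bait_mid = (rec[bs] + rec[be]) // 2
            for pid, prow in sub.iterrows():
                if not include_bait_dmps:
                    in_bait = (prow["chrom"] == rec[bc]
                               and rec[bs] <= prow["pt"] < rec[be])
                    if in_bait:
                        continue
                rows.append({
                    "probe_id": pid,
                    "gene": rec["gene"],
                    "interaction_id": int(idx),
                    "distance_to_bait": int(abs(prow["pt"] - bait_mid))
                    if prow["chrom"] == rec[bc] else -1,
                })
    if skipped:
        logger.info("skipped %d interactions with no TSS on either end",
                    skipped)
    out = pd.DataFrame(rows, columns=["probe_id", "gene", "interaction_id",
                                      "distance_to_bait"])
    return out.drop_duplicates(["probe_id", "interaction_id"]).reset_index(
        drop=True)
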