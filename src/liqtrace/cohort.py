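"""Cross-patient aggregation: cascade summary tables and candidate overlaps."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import pandas as pd

from liqtrace.filtering import CandidateSet

MAX_OVERLAP_PATIENTS = 10


@dataclass
class OverlapTable:
    """Exclusive-region counts of candidate sets across patients.

    ``regions`` maps each non-empty patient subset S to the number of features
    that are candidates in exactly the patients of S (Venn-diagram regions).
    Singleton subsets give each patient's exclusive count.  The region counts
    partition the union of all candidate sets.
    """

    patient_ids: list[str]
    regions: dict[frozenset[str], int]

    def count(self, *patients: str) -> int:
        return self.regions.get(frozenset(patients), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subset, n in self.regions.items():
            rows.append({"region": "+".join(sorted(subset)), "size": len(subset), "exclusive_count": n})
        df = pd.DataFrame(rows, columns=["region", "size", "exclusive_count"])
        return df.sort_values(["size", "region"]).reset_index(drop=True)


def cascade_table(candidate_sets: Mapping[str, CandidateSet]) -> pd.DataFrame:
    """One row per patient with the four cascade counts.

    Columns: universe (all features), filter1 (expressed pre-surgery),
    filter2 (also downregulated post-surgery), filter3 (also rebounding at
    recurrence = candidates).  Rows are non-increasing left to right.
    """
    if not candidate_sets:
        raise ValueError("cascade_table needs at least one patient")
    rows = []
    for pid, cs in candidate_sets.items():
        u, f1, f2, f3 = cs.cascade_counts
        rows.append({"patient_id": pid, "universe": u, "filter1": f1, "filter2": f2, "filter3": f3})
    return pd.DataFrame(rows, columns=["patient_id", "universe", "filter1", "filter2", "filter3"])


def overlap_counts(candidates: Mapping[str, frozenset[str] | set[str]]) -> OverlapTable:
    """Exact exclusive-region counts for every non-empty patient subset.

    Each feature in the union of the candidate sets is assigned to the region
    of exactly the patients that carry it; all 2^k - 1 subsets are reported
    (zero for empty regions).  Limited to 10 patients.
    """
    pids = list(candidates)
    if len(pids) < 2:
        raise ValueError("overlap_counts needs at least two patients")
    if len(pids) > MAX_OVERLAP_PATIENTS:
        raise ValueError(
            f"overlap over {len(pids)} patients unsupported (max {MAX_OVERLAP_PATIENTS})"
        )
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(pids) + 1):
        for combo in combinations(sorted(pids), r):
            regions[frozenset(combo)] = 0
    union = set().union(*candidates.values())
    for feature in union:
        members = frozenset(p for p in pids if feature in candidates[p])
        regions[members] += 1
    return OverlapTable(patient_ids=sorted(pids), regions=regions)


def collapse_to_genes(
    candidates: Mapping[str, frozenset[str] | set[str]],
    feature_to_gene: Mapping[str, str],
) -> dict[str, frozenset[str]]:
    """Map feature-level candidate sets to gene level before overlap counting.

    The same gene is often detected on different exons in different patients;
    collapsing with a user-supplied feature-to-gene map makes those count as
    an overlap.  Features absent from the map keep their own ID.
    """
    return {
        pid: frozenset(feature_to_gene.get(f, f) for f in feats)
        for pid, feats in candidates.items()
    }


def read_gene_map(path) -> dict[str, str]:
    """Two-column TSV (feature_id, gene_id) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("gene map must have two tab-separated columns")
    return dict(zip(df[0], df[1]))


__all__ = [
    "MAX_OVERLAP_PATIENTS",
    "OverlapTable",
    "cascade_table",
    "collapse_to_genes",
    "overlap_counts",
    "read_gene_map",
]
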