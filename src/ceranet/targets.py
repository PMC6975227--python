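"""CLIP-supported miRNA-target relationships.

Candidate target sites come either from an external prediction table or from
a simple seed-complementarity scan (exact match of the reverse complement of
miRNA positions 2-8 in the 3'UTR of an mRNA or the full lncRNA transcript).
Candidates are then filtered against AGO CLIP-seq binding intervals: a site is
retained only if it overlaps at least one AGO peak on the same transcript by
at least one base. All coordinates are 0-based half-open (BED convention);
strand is transcript-space and therefore ignored.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

_COMPLEMENT = str.maketrans("ACGUacgu", "UGCAugca")
_VALID = set("ACGTUacgtu")

CANDIDATE_COLUMNS = ["mirna_id", "target_id", "target_class", "site_start", "site_end"]


def _check_seq(name: str, seq: str) -> str:
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"sequence {name!r} contains invalid characters {sorted(bad)}"
        )
    return seq.upper().replace("T", "U")


def seed_match_pattern(mirna_seq: str) -> str:
    """Reverse complement of the miRNA seed (positions 2-8, a 7-mer)."""
    if len(mirna_seq) < 8:
        raise ValueError("miRNA sequence must be at least 8 nt for a 2-8 seed")
    seed = mirna_seq[1:8]
    return seed.translate(_COMPLEMENT)[::-1]


def predict_seed_targets(
    mirna_seqs: dict, target_seqs: dict, target_class: dict
) -> pd.DataFrame:
    """Scan target regions for exact seed complements.

    ``target_seqs`` maps target id to the searched region's sequence (3'UTR
    for mRNA, full transcript for lncRNA); coordinates in the output refer to
    that region. One candidate row per match occurrence.
    """
    rows = []
    targets = {
        tid: _check_seq(tid, seq) for tid, seq in target_seqs.items()
    }
    for mid in sorted(mirna_seqs):
        pattern = seed_match_pattern(_check_seq(mid, mirna_seqs[mid]))
        for tid in sorted(targets):
            seq = targets[tid]
            start = seq.find(pattern)
            while start != -1:
                rows.append((mid, tid, target_class[tid], start, start + 7))
                start = seq.find(pattern, start + 1)
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def filter_by_clip(candidates: pd.DataFrame, clip_sites: pd.DataFrame) -> pd.DataFrame:
    """Retain candidates overlapping >= 1 AGO CLIP interval on their transcript.

    Overlap means an intersection of at least one base under the half-open
    convention (abutting intervals do not overlap). Input row order is kept;
    transcripts with no CLIP data simply never overlap. Idempotent.
    """
    trees: dict[str, IntervalTree] = {}
    for row in clip_sites.itertuples(index=False):
        trees.setdefault(str(row.transcript_id), IntervalTree()).addi(
            int(row.start), int(row.end)
        )
    keep = [
        bool(
            trees.get(str(row.target_id))
            and trees[str(row.target_id)].overlap(
                int(row.site_start), int(row.site_end)
            )
        )
        for row in candidates.itertuples(index=False)
    ]
    return candidates.loc[keep].reset_index(drop=True)


def collapse_to_pairs(candidates: pd.DataFrame) -> pd.DataFrame:
    """Reduce site-level candidates to unique (miRNA, target) pairs.

    Multiple sites supporting a pair are counted in ``site_count``; a pair is
    one regulatory relationship regardless of its number of sites.
    """
    if len(candidates) == 0:
        return pd.DataFrame(
            columns=["mirna_id", "target_id", "target_class", "site_count"]
        )
    return (
        candidates.groupby(
            ["mirna_id", "target_id", "target_class"], as_index=False, sort=True
        )
        .size()
        .rename(columns={"size": "site_count"})
    )


def read_clip_bed(path) -> pd.DataFrame:
    """Read AGO peaks from a BED3(+name) file; extra columns are ignored."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        source = parts[3] if len(parts) > 3 else ""
        rows.append((parts[0], int(parts[1]), int(parts[2]), source))
    return pd.DataFrame(rows, columns=["transcript_id", "start", "end", "source"])


def read_candidates_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CANDIDATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    return df
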