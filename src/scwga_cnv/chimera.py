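"""Read-pair orientation classification for WGA chimera profiling.

Amplification chemistries create artifactual junctions (chimeras) that
surface in paired-end data as discordant read-pair orientations. In a
proper pair the mates point inward, towards each other; the discordant
signatures are:

* outward — mates point away from each other: tandem-duplication-like,
  the dominant artifact of PCR-based chemistries;
* interchrom — mates on different chromosomes: translocation-like;
* other — mates on the same strand (FF/RR): inversion-like, the classic
  MDA chimera signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

PAIR_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
                "mq1", "mq2"]


@dataclass
class PairRecord:
    """One read pair: mate coordinates, strands and mapping qualities."""

    chrom1: str
    pos1: int
    strand1: str | None
    chrom2: str
    pos2: int
    strand2: str | None
    mq1: int = 60
    mq2: int = 60
    insert: int | None = None
    duplicate: bool = False


def classify_pair(pair: PairRecord) -> str | None:
    """Orientation category of a read pair, or None when unclassifiable.

    Mates on different chromosomes are 'interchrom'. Otherwise, with the
    mates ordered left/right by position (ties broken '+' first), the pair is
    'inward' when the left mate is on '+' and the right on '-', 'outward' for
    the reverse, and 'other' when both mates share a strand. Symmetric under
    mate swap.
    """
    if pair.strand1 not in ("+", "-") or pair.strand2 not in ("+", "-"):
        return None
    if pair.chrom1 != pair.chrom2:
        return "interchrom"
    if pair.strand1 == pair.strand2:
        return "other"
    left = (pair.pos1, 0 if pair.strand1 == "+" else 1)
    right = (pair.pos2, 0 if pair.strand2 == "+" else 1)
    if left <= right:
        left_strand = pair.strand1
    else:
        left_strand = pair.strand2
    return "inward" if left_strand == "+" else "outward"


def summarize_chimeras(records: list[PairRecord],
                       mq_min: int = 0) -> dict[str, float]:
    """Per-cell fractions of each orientation category.

    Pairs flagged as duplicates are dropped; the MAPQ floor applies to both
    mates. Fractions are over classifiable records and sum to 1; the raw
    counts and the unclassifiable tally are returned alongside.
    """
    counts = {"inward": 0, "outward": 0, "interchrom": 0, "other": 0}
    unclassifiable = 0
    for rec in records:
        if rec.duplicate or rec.mq1 < mq_min or rec.mq2 < mq_min:
            continue
        cat = classify_pair(rec)
        if cat is None:
            unclassifiable += 1
        else:
            counts[cat] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no classifiable read pairs")
    out: dict[str, float] = {k: v / total for k, v in counts.items()}
    out["n_classifiable"] = total
    out["n_unclassifiable"] = unclassifiable
    return out


def pairs_from_tsv(path) -> list[PairRecord]:
    """Read pair records from a TSV with the PAIR_COLUMNS layout."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PAIR_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"pair table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(PairRecord(str(row.chrom1), int(row.pos1),
                                  str(row.strand1), str(row.chrom2),
                                  int(row.pos2), str(row.strand2),
                                  int(getattr(row, "mq1", 60)),
                                  int(getattr(row, "mq2", 60))))
    return records


def pairs_to_tsv(records: list[PairRecord], path) -> None:
    pd.DataFrame([(r.chrom1, r.pos1, r.strand1, r.chrom2, r.pos2, r.strand2,
                   r.mq1, r.mq2) for r in records],
                 columns=PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def pairs_from_sam(path, mq_min: int = 0) -> list[PairRecord]:
    """Pair records from alignment records (SAM flag semantics, needs pysam).

    Uses the primary alignment of read 1 of each pair: strand bits 0x10/0x20
    and RNEXT/PNEXT give the mate geometry; duplicates (0x400) are flagged.
    """
    import pysam  # optional dependency

    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if (aln.is_unmapped or aln.mate_is_unmapped or aln.is_secondary
                    or aln.is_supplementary or not aln.is_read1):
                continue
            records.append(PairRecord(
                aln.reference_name, aln.reference_start,
                "-" if aln.is_reverse else "+",
                aln.next_reference_name, aln.next_reference_start,
                "-" if aln.mate_is_reverse else "+",
                aln.mapping_quality, aln.mapping_quality,
                duplicate=aln.is_duplicate))
    return records
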