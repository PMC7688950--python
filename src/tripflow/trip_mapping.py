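"""Replicate-concordant assignment of genomic integration sites to barcodes.

Mapped reads (one junction per barcode, two replicate libraries) scatter by a
few bp; reads are clustered per barcode/replicate, the cluster with the most
reads is the *top candidate*, and a site is assigned only when the top
candidates of both replicates agree (same chromosome and strand, positions
within the merge window).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

STATUS_ASSIGNED = "assigned"
STATUS_DISCORDANT = "discordant"
STATUS_SINGLE_REPLICATE = "single_replicate"
STATUS_UNMAPPED = "unmapped"

READ_COLUMNS = ["barcode", "chrom", "pos", "strand", "replicate"]


class Locus(NamedTuple):
    chrom: str
    pos: int
    strand: str
    count: int


@dataclass(frozen=True)
class IntegrationSite:
    barcode: str
    chrom: str | None
    pos: int | None
    strand: str | None
    support_rep1: int
    support_rep2: int
    status: str


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "chrom": str, "strand": str})
    missing = set(READ_COLUMNS) - {"replicate"} - set(df.columns)
    if missing:
        raise ValueError(f"mapped-read table missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def sam_to_reads(path: str | Path, replicate: int, barcode_tag: str = "BC") -> pd.DataFrame:
    """Convert mapped SAM records (barcode in a tag) to a mapped-read table."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or not aln.has_tag(barcode_tag):
                continue
            rows.append(
                {
                    "barcode": aln.get_tag(barcode_tag),
                    "chrom": aln.reference_name,
                    "pos": aln.reference_start,
                    "strand": "-" if aln.is_reverse else "+",
                    "replicate": replicate,
                }
            )
    return pd.DataFrame(rows, columns=READ_COLUMNS)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def cluster_reads(reads: pd.DataFrame, merge_window: int = 10) -> list[Locus]:
    """Cluster one barcode+replicate's reads by chrom/strand proximity.

    Reads on the same chrom+strand whose sorted positions are chained by gaps
    <= ``merge_window`` form one cluster; the representative position is the
    cluster's modal read position (ties -> smallest).  Read counts are
    conserved across clusters.
    """
    if merge_window < 0:
        raise ValueError("merge_window must be >= 0")
    loci: list[Locus] = []
    for (chrom, strand), grp in reads.groupby(["chrom", "strand"], sort=True):
        pos = np.sort(grp["pos"].to_numpy())
        breaks = np.flatnonzero(np.diff(pos) > merge_window) + 1
        for chunk in np.split(pos, breaks):
            vals, counts = np.unique(chunk, return_counts=True)
            rep = int(vals[np.argmax(counts)])  # argmax -> first (smallest) mode
            loci.append(Locus(str(chrom), rep, str(strand), int(chunk.size)))
    return loci


def top_candidate(clusters: list[Locus]) -> Locus | None:
    """Cluster with the maximal read count; a tie for the maximum (or no
    clusters at all) yields None."""
    if not clusters:
        return None
    best = max(c.count for c in clusters)
    winners = [c for c in clusters if c.count == best]
    return winners[0] if len(winners) == 1 else None


def assign_sites(
    reads_rep1: pd.DataFrame,
    reads_rep2: pd.DataFrame,
    merge_window: int = 10,
    barcodes: list[str] | None = None,
) -> pd.DataFrame:
    """Assign one integration site per barcode from two replicate read tables.

    Statuses: ``assigned`` (both replicates give a top candidate on the same
    chrom+strand within ``merge_window``; site = replicate-1 representative),
    ``discordant`` (tops disagree or are tied), ``single_replicate`` (reads in
    only one replicate), ``unmapped`` (no reads).
    """
    g1 = dict(tuple(reads_rep1.groupby("barcode")))
    g2 = dict(tuple(reads_rep2.groupby("barcode")))
    if barcodes is None:
        barcodes = sorted(set(g1) | set(g2))

    rows = []
    for b in barcodes:
        r1, r2 = g1.get(b), g2.get(b)
        site = dict(barcode=b, chrom=None, pos=None, strand=None,
                    support_rep1=0, support_rep2=0, status=STATUS_UNMAPPED)
        if r1 is None and r2 is None:
            rows.append(site)
            continue
        if r1 is None or r2 is None:
            site["status"] = STATUS_SINGLE_REPLICATE
            rows.append(site)
            continue
        t1 = top_candidate(cluster_reads(r1, merge_window))
        t2 = top_candidate(cluster_reads(r2, merge_window))
        if t1 is None or t2 is None:
            site["status"] = STATUS_DISCORDANT
        elif (
            t1.chrom == t2.chrom
            and t1.strand == t2.strand
            and abs(t1.pos - t2.pos) <= merge_window
        ):
            site.update(
                chrom=t1.chrom, pos=t1.pos, strand=t1.strand,
                support_rep1=t1.count, support_rep2=t2.count,
                status=STATUS_ASSIGNED,
            )
        else:
            site["status"] = STATUS_DISCORDANT
        rows.append(site)

    df = pd.DataFrame(rows)
    df["pos"] = df["pos"].astype("Int64")
    return df
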