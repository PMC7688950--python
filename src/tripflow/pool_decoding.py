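"""Combinatorial k-of-n pooling designs and barcode -> clone decoding.

Each clone is split into a unique *signature* of exactly ``weight`` pools out
of ``n_pools``.  Sequencing each pool yields a barcode x pool count table;
decoding recovers, for every barcode, the set of positive pools and matches it
against the design, handling merged signatures (one barcode observed in the
union of two clones' pools) and clones carrying multiple barcodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

ASSIGNED = "assigned"
MERGED_PAIR = "merged_pair"
UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"


class CapacityError(ValueError):
    """More clones requested than the design can uniquely encode."""


@dataclass
class PoolingDesign:
    """clone_id -> frozenset of ``weight`` pool indices (0-based)."""

    n_pools: int
    weight: int
    assignments: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        sigs = list(self.assignments.values())
        if any(len(s) != self.weight for s in sigs):
            raise ValueError("every signature must have exactly `weight` pools")
        if len(set(sigs)) != len(sigs):
            raise ValueError("signatures must be pairwise distinct")
        if any(max(s, default=-1) >= self.n_pools or min(s, default=0) < 0 for s in sigs):
            raise ValueError("pool index out of range")

    def signature_of(self, clone_id: str) -> frozenset[int]:
        return self.assignments[clone_id]

    @property
    def by_signature(self) -> dict[frozenset[int], str]:
        return {sig: clone for clone, sig in self.assignments.items()}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("clone_id\tpools\n")
            for clone, sig in self.assignments.items():
                fh.write(f"{clone}\t{','.join(map(str, sorted(sig)))}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, n_pools: int, weight: int) -> "PoolingDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        assignments = {
            row.clone_id: frozenset(int(p) for p in row.pools.split(","))
            for row in df.itertuples()
        }
        return cls(n_pools=n_pools, weight=weight, assignments=assignments)


@dataclass
class PoolCountTable:
    """Barcode x pool nonnegative integer counts.

    ``counts`` is indexed by barcode sequence with integer pool-index columns
    0..n_pools-1.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts.columns = [int(c) for c in self.counts.columns]

    @property
    def barcodes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def pools(self) -> list[int]:
        return list(self.counts.columns)

    @property
    def pool_depths(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.columns = [f"pool{c:02d}" for c in out.columns]
        out.to_csv(path, sep="\t", index_label="barcode")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PoolCountTable":
        df = pd.read_csv(path, sep="\t", index_col="barcode")
        df.columns = [int(str(c).replace("pool", "")) for c in df.columns]
        return cls(counts=df)


@dataclass
class DecodeResult:
    """Per-barcode decode outcome plus per-clone multi-barcode exclusions.

    ``table`` columns: status, clone, clone2 (merged pairs only),
    positive_pools (comma-joined).  ``excluded_multibarcode`` lists clones
    matched by >= 2 distinct barcodes with identical signatures.
    """

    table: pd.DataFrame
    excluded_multibarcode: set[str] = field(default_factory=set)

    def status_counts(self) -> dict[str, int]:
        return self.table["status"].value_counts().to_dict()

    def assigned_clone(self, barcode: str) -> str | None:
        row = self.table.loc[barcode]
        return row["clone"] if row["status"] == ASSIGNED else None

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="barcode")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def design_capacity(n_pools: int, weight: int) -> int:
    """Number of distinct signatures: C(n_pools, weight), exact."""
    if weight < 0 or n_pools < 0:
        raise ValueError("n_pools and weight must be nonnegative")
    if weight > n_pools:
        raise ValueError(f"weight {weight} exceeds n_pools {n_pools}")
    return math.comb(n_pools, weight)


def make_design(
    n_clones: int,
    n_pools: int,
    weight: int,
    scheme: str = "lexicographic",
    clone_ids: list[str] | None = None,
) -> PoolingDesign:
    """Deterministically assign the first ``n_clones`` signatures.

    ``lexicographic`` enumerates combinations in lexicographic order;
    ``balanced`` greedily picks, at each step, the unused signature whose
    pools currently host the fewest clones (ties broken lexicographically).
    """
    cap = design_capacity(n_pools, weight)
    if n_clones > cap:
        raise CapacityError(
            f"{n_clones} clones exceed capacity C({n_pools},{weight}) = {cap}"
        )
    if clone_ids is None:
        clone_ids = [f"clone{i:04d}" for i in range(n_clones)]
    elif len(clone_ids) != n_clones:
        raise ValueError("clone_ids length must equal n_clones")

    all_sigs = [frozenset(c) for c in combinations(range(n_pools), weight)]
    if scheme == "lexicographic":
        chosen = all_sigs[:n_clones]
    elif scheme == "balanced":
        loads = np.zeros(n_pools, dtype=int)
        used = set()
        chosen = []
        sig_keys = [tuple(sorted(s)) for s in all_sigs]
        for _ in range(n_clones):
            best = min(
                (s for s in range(len(all_sigs)) if s not in used),
                key=lambda s: (int(loads[list(all_sigs[s])].sum()), sig_keys[s]),
            )
            used.add(best)
            chosen.append(all_sigs[best])
            loads[list(all_sigs[best])] += 1
    else:
        raise ValueError(f"unknown scheme: {scheme!r}")

    return PoolingDesign(
        n_pools=n_pools,
        weight=weight,
        assignments=dict(zip(clone_ids, chosen)),
    )


def _normalized_row(
    table: PoolCountTable, barcode: str, depth_normalize: bool
) -> pd.Series:
    row = table.counts.loc[barcode].astype(float)
    if depth_normalize:
        depths = table.pool_depths.astype(float)
        row = row.where(depths == 0, row / depths.replace(0, np.nan)).fillna(0.0)
    return row


def call_positive_pools(
    table: PoolCountTable,
    barcode: str,
    depth_normalize: bool = True,
    rel_threshold: float = 0.2,
) -> frozenset[int]:
    """Pools whose (depth-normalized) count reaches ``rel_threshold`` times the
    barcode's maximum normalized count.  All-zero rows yield the empty set."""
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must be in (0, 1)")
    row = _normalized_row(table, barcode, depth_normalize)
    top = row.max()
    if top <= 0:
        return frozenset()
    return frozenset(int(p) for p, v in row.items() if v >= rel_threshold * top)


def decode(
    table: PoolCountTable,
    design: PoolingDesign,
    rel_threshold: float = 0.2,
    depth_normalize: bool = True,
) -> DecodeResult:
    """Decode every barcode in ``table`` against ``design``.

    1. Positive sets of exactly ``weight`` pools equal to a clone signature
       -> ``assigned``.
    2. Positive sets larger than ``weight`` are matched against unions of
       signatures of unordered pairs of still-unassigned clones: a unique
       match -> ``merged_pair``; several matches -> ``ambiguous``.
    3. Clones assigned via >= 2 distinct barcodes (identical signature) are
       flagged ``excluded_multibarcode``.
    4. Everything else -> ``unassigned``.
    """
    by_sig = design.by_signature
    positive = {
        b: call_positive_pools(table, b, depth_normalize, rel_threshold)
        for b in table.barcodes
    }

    rows: dict[str, dict] = {}
    clone_hits: dict[str, list[str]] = {}
    for b, pos in positive.items():
        rows[b] = {
            "status": UNASSIGNED,
            "clone": "",
            "clone2": "",
            "positive_pools": ",".join(map(str, sorted(pos))),
        }
        if len(pos) == design.weight and pos in by_sig:
            clone = by_sig[pos]
            rows[b].update(status=ASSIGNED, clone=clone)
            clone_hits.setdefault(clone, []).append(b)

    assigned_clones = set(clone_hits)
    unassigned_clones = [c for c in design.assignments if c not in assigned_clones]
    for b, pos in positive.items():
        if rows[b]["status"] != UNASSIGNED or len(pos) <= design.weight:
            continue
        # only clones whose full signature lies inside the positive set can
        # participate in a merged readout
        cands = [c for c in unassigned_clones if design.assignments[c] <= pos]
        matches = [
            (a, c)
            for a, c in combinations(cands, 2)
            if design.assignments[a] | design.assignments[c] == pos
        ]
        if len(matches) == 1:
            a, c = matches[0]
            rows[b].update(status=MERGED_PAIR, clone=a, clone2=c)
        elif len(matches) > 1:
            rows[b]["status"] = AMBIGUOUS

    excluded = {c for c, bars in clone_hits.items() if len(bars) >= 2}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "barcode"
    return DecodeResult(table=df, excluded_multibarcode=excluded)
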