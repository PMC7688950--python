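"""Chromatin features at integration sites: windowed signal enrichment and
nearest-distance to segmentation states.

Two feature families are produced per site: ``enr_<TF>`` — the bin-overlap-
weighted mean of a binned fold-change signal track over a window centred on
the site — and ``dist_<state>`` — the distance in bp from the site to the
nearest interval of each segmentation state (0 when the site lies inside one).
Coordinates are 0-based half-open throughout (BED-compatible).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: 25-state segmentation vocabulary (mnemonic labels).
CHROMHMM_STATES: tuple[str, ...] = (
    "Tss", "TssF", "PromF", "PromP", "Enh", "EnhF", "EnhW", "EnhWF",
    "Pol2", "Gen5p", "Gen3p", "Elon", "ElonW", "Ctcf", "CtcfO",
    "DnaseD", "DnaseU", "Faire", "FaireW", "H4K20", "Low",
    "Repr", "ReprD", "ReprW", "Quies",
)

#: Coarse functional grouping of the 25 states (metadata only; features are
#: always computed per individual state).
STATE_GROUPS: dict[str, str] = {
    "Tss": "promoter", "TssF": "promoter", "PromF": "promoter", "PromP": "promoter",
    "Enh": "enhancer", "EnhF": "enhancer", "EnhW": "enhancer", "EnhWF": "enhancer",
    "Pol2": "transcribed", "Gen5p": "transcribed", "Gen3p": "transcribed",
    "Elon": "transcribed", "ElonW": "transcribed",
    "Ctcf": "insulator", "CtcfO": "insulator",
    "DnaseD": "open", "DnaseU": "open", "Faire": "open", "FaireW": "open",
    "H4K20": "repressed", "Repr": "repressed", "ReprD": "repressed", "ReprW": "repressed",
    "Low": "quiescent", "Quies": "quiescent",
}


@dataclass
class SignalTrack:
    """Uniformly binned nonnegative signal (fold change over control).

    ``values[chrom]`` holds one value per ``bin_size``-bp bin; the final bin
    may be short (``chrom_lengths`` records the true length).
    """

    name: str
    bin_size: int
    values: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(v)) or (v < 0).any():
                raise ValueError(f"track {self.name}/{chrom}: values must be finite and >= 0")
            n_expected = -(-self.chrom_lengths[chrom] // self.bin_size)
            if len(v) != n_expected:
                raise ValueError(
                    f"track {self.name}/{chrom}: {len(v)} bins, expected {n_expected}"
                )
            self.values[chrom] = v

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.values):
                length = self.chrom_lengths[chrom]
                for i, v in enumerate(self.values[chrom]):
                    start = i * self.bin_size
                    end = min(start + self.bin_size, length)
                    # .17g round-trips float64 exactly through text
                    fh.write(f"{chrom}\t{start}\t{end}\t{float(v):.17g}\n")

    @classmethod
    def from_bedgraph(cls, path: str | Path, name: str | None = None) -> "SignalTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
            dtype={"chrom": str}, float_precision="round_trip",
        )
        bin_size = int((df["end"] - df["start"]).max())
        values: dict[str, np.ndarray] = {}
        lengths: dict[str, int] = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            grp = grp.sort_values("start")
            if not (grp["start"].to_numpy() == np.arange(len(grp)) * bin_size).all():
                raise ValueError(f"{path}: bins on {chrom} do not tile uniformly")
            values[str(chrom)] = grp["value"].to_numpy(dtype=float)
            lengths[str(chrom)] = int(grp["end"].max())
        return cls(
            name=name or Path(path).stem, bin_size=bin_size,
            values=values, chrom_lengths=lengths,
        )


@dataclass
class StateSegmentation:
    """Sorted, non-overlapping labelled intervals tiling each chromosome."""

    intervals: pd.DataFrame  # chrom, start, end, state
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        df = self.intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        unknown = set(df["state"]) - set(self.states)
        if unknown:
            raise ValueError(f"states outside vocabulary: {sorted(unknown)}")
        for chrom, grp in df.groupby("chrom"):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping intervals on {chrom}")
        self.intervals = df

    def to_bed(self, path: str | Path) -> None:
        self.intervals.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(
        cls, path: str | Path, states: tuple[str, ...] | None = None
    ) -> "StateSegmentation":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "state"],
            dtype={"chrom": str, "state": str},
        )
        if states is None:
            states = tuple(sorted(df["state"].unique()))
        return cls(intervals=df, states=states)


@dataclass
class FeatureMatrix:
    """Clones x features table with missingness mask and sidecar metadata."""

    X: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def mask(self) -> pd.DataFrame:
        return self.X.isna()

    def to_tsv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        self.X.to_csv(path, sep="\t", index_label="clone_id")
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump(self.meta, fh, indent=2)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        return cls(X=pd.read_csv(path, sep="\t", index_col="clone_id"))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def window_enrichment(
    track: SignalTrack, chrom: str, pos: int, window_bp: int = 50_000
) -> float:
    """Overlap-weighted mean of the track over ``[pos - w/2, pos + w/2)``,
    clipped at chromosome ends; NaN if the chromosome is absent."""
    if chrom not in track.values:
        return float("nan")
    length = track.chrom_lengths[chrom]
    lo = max(0, pos - window_bp // 2)
    hi = min(length, pos + window_bp // 2)
    if hi <= lo:
        return float("nan")
    bs = track.bin_size
    first, last = lo // bs, (hi - 1) // bs
    vals = track.values[chrom][first: last + 1]
    edges = np.arange(first, last + 2) * bs
    overlap = np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo)
    return float(np.average(vals, weights=overlap))


def distance_to_state(
    seg: StateSegmentation, chrom: str, pos: int, state_label: str
) -> float:
    """Distance in bp from ``pos`` to the nearest same-chromosome interval of
    ``state_label``: 0 inside an interval, else the gap to the closest
    interval base.  NaN when the state has no interval on that chromosome."""
    if state_label not in seg.states:
        raise ValueError(f"unknown state: {state_label!r}")
    df = seg.intervals
    sub = df[(df["chrom"] == chrom) & (df["state"] == state_label)]
    if sub.empty:
        return float("nan")
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    # gap to interval [start, end): pos < start -> start - pos;
    # pos >= end -> pos - (end - 1); inside -> 0
    d = np.maximum(np.maximum(start - pos, pos - (end - 1)), 0)
    return float(d.min())


def build_matrix(
    sites: pd.DataFrame,
    tracks: list[SignalTrack],
    seg: StateSegmentation | None = None,
    expression: pd.DataFrame | None = None,
    window_bp: int = 50_000,
    expression_floor: float = 1.0,
) -> FeatureMatrix:
    """Assemble the clones x features matrix for assigned sites.

    ``sites`` needs columns clone_id/chrom/pos (strand, if present, is
    ignored: features are strand-agnostic).  When ``expression`` (indexed by
    clone_id with mean_avg/cv2_avg) is given, it is joined onto the matrix and
    clones whose mean falls below ``expression_floor`` — reporters that lost
    expression — are dropped.
    """
    if "clone_id" in sites.columns:
        sites = sites.set_index("clone_id")
    elif "barcode" in sites.columns:
        sites = sites.set_index("barcode")
    rows = {}
    for clone, site in sites.iterrows():
        feats = {}
        for tr in tracks:
            feats[f"enr_{tr.name}"] = window_enrichment(
                tr, site["chrom"], int(site["pos"]), window_bp
            )
        if seg is not None:
            for st in seg.states:
                feats[f"dist_{st}"] = distance_to_state(
                    seg, site["chrom"], int(site["pos"]), st
                )
        rows[clone] = feats
    X = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    X.index.name = "clone_id"

    meta = {
        "window_bp": window_bp,
        "features": {
            **{f"enr_{t.name}": {"type": "enrichment", "source": t.name} for t in tracks},
            **(
                {f"dist_{s}": {"type": "distance", "state": s,
                               "group": STATE_GROUPS.get(s, "other")}
                 for s in seg.states}
                if seg is not None else {}
            ),
        },
    }

    if expression is not None:
        expr = expression.set_index("clone_id") if "clone_id" in expression.columns else expression
        keep = expr.index[expr["mean_avg"] >= expression_floor]
        X = X.loc[X.index.intersection(keep)]
        X = X.join(expr.loc[X.index, ["mean_avg", "cv2_avg"]])
        meta["expression_floor"] = expression_floor

    if X.empty:
        raise ValueError("no clones overlap between sites and expression table")
    return FeatureMatrix(X=X, meta=meta)
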