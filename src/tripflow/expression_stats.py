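"""Flow-cytometry gating and per-clone expression mean / CV² statistics.

Events are gated to a central FSC x SSC quantile box per well (clone x
replicate), internal-control cells are split off by IRFP intensity, and the
reporter channel is summarized as mean, unbiased variance and CV² =
variance / mean².  CV² is computed on linear intensities (log axes in plots
are display-only).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

EVENT_COLUMNS = ["fsc", "ssc", "clover", "irfp"]


class EmptyGateError(ValueError):
    """No events survive the gate."""


class UnimodalIrfpError(ValueError):
    """Automatic IRFP threshold requested but the distribution is unimodal."""


@dataclass
class GateSpec:
    """Per-axis quantile window (``mode='quantile'``, the default, recomputed
    per well) or fixed intensity bounds (``mode='fixed'``)."""

    fsc_window: tuple[float, float] = (0.375, 0.625)
    ssc_window: tuple[float, float] = (0.375, 0.625)
    mode: str = "quantile"
    fsc_bounds: tuple[float, float] | None = None
    ssc_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for lo, hi in (self.fsc_window, self.ssc_window):
            if not 0 <= lo < hi <= 1:
                raise ValueError("quantile windows need 0 <= low < high <= 1")
        if self.mode not in ("quantile", "fixed"):
            raise ValueError(f"unknown gate mode: {self.mode!r}")
        if self.mode == "fixed" and (self.fsc_bounds is None or self.ssc_bounds is None):
            raise ValueError("fixed mode requires fsc_bounds and ssc_bounds")


@dataclass
class ExpressionSummary:
    clone_id: str
    replicate: int
    n_cells: int
    mean: float
    variance: float
    cv2: float
    low_n: bool = False


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _gate_mask(df: pd.DataFrame, gate: GateSpec) -> np.ndarray:
    if gate.mode == "fixed":
        f_lo, f_hi = gate.fsc_bounds
        s_lo, s_hi = gate.ssc_bounds
    else:
        f_lo, f_hi = df["fsc"].quantile(list(gate.fsc_window))
        s_lo, s_hi = df["ssc"].quantile(list(gate.ssc_window))
    keep = df["fsc"].between(f_lo, f_hi) & df["ssc"].between(s_lo, s_hi)
    return keep.to_numpy()


def gate_events(events: pd.DataFrame, gate: GateSpec | None = None) -> pd.DataFrame:
    """Keep events inside the FSC and SSC windows.

    Quantile windows are evaluated within each (clone_id, replicate) group
    when those columns are present, else on the whole table.
    """
    gate = gate or GateSpec()
    keys = [c for c in ("clone_id", "replicate") if c in events.columns]
    if keys and gate.mode == "quantile":
        keep = np.zeros(len(events), dtype=bool)
        for pos in events.groupby(keys, sort=False).indices.values():
            keep[pos] = _gate_mask(events.iloc[pos], gate)
        gated = events.iloc[np.flatnonzero(keep)]
    else:
        gated = events[_gate_mask(events, gate)]
    if len(events) and gated.empty:
        raise EmptyGateError("gate removed every event")
    return gated


def auto_irfp_cutoff(irfp: np.ndarray, min_separation: float = 1.5) -> float:
    """Threshold between the two modes of a 2-component Gaussian split of
    log10(IRFP); raises :class:`UnimodalIrfpError` when the components are not
    separated by at least ``min_separation`` of the wider component's sd."""
    from sklearn.mixture import GaussianMixture

    x = np.log10(np.asarray(irfp, dtype=float) + 1e-9).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, n_init=3, random_state=0).fit(x)
    means = np.sort(gm.means_.ravel())
    sds = np.sqrt(gm.covariances_.ravel())
    if (means[1] - means[0]) < min_separation * sds.max():
        raise UnimodalIrfpError(
            "log-IRFP looks unimodal; supply an explicit irfp cutoff"
        )
    return float(10 ** means.mean())


def split_control(
    events: pd.DataFrame, irfp_cutoff: float | str = "auto"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition events into (experimental, internal control) by IRFP;
    control cells are those with irfp >= cutoff."""
    if irfp_cutoff == "auto":
        irfp_cutoff = auto_irfp_cutoff(events["irfp"].to_numpy())
    is_ctrl = events["irfp"] >= irfp_cutoff
    return events[~is_ctrl], events[is_ctrl]


def summarize(
    clover: np.ndarray | pd.Series,
    clone_id: str = "",
    replicate: int = 0,
    min_cells: int = 1000,
) -> ExpressionSummary:
    """Mean, unbiased variance and CV² of one well's reporter intensities."""
    x = np.asarray(clover, dtype=float)
    if x.size == 0:
        raise EmptyGateError(f"no events to summarize for {clone_id}/{replicate}")
    mean = float(x.mean())
    var = float(x.var(ddof=1)) if x.size > 1 else 0.0
    cv2 = var / mean**2 if mean > 0 else float("nan")
    return ExpressionSummary(
        clone_id=clone_id, replicate=int(replicate), n_cells=int(x.size),
        mean=mean, variance=var, cv2=cv2, low_n=x.size < min_cells,
    )


def process_events(
    events: pd.DataFrame,
    gate: GateSpec | None = None,
    irfp_cutoff: float | str = "auto",
    min_cells: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gate -> IRFP split -> summarize, per (clone_id, replicate) well.

    Returns (experimental summaries, control summaries) as DataFrames; wells
    emptied by the gate are dropped (they appear in neither output).
    """
    exp_rows, ctrl_rows = [], []
    for (clone, rep), well in events.groupby(["clone_id", "replicate"], sort=True):
        try:
            gated = gate_events(well, gate)
        except EmptyGateError:
            continue
        exp, ctrl = split_control(gated, irfp_cutoff)
        if len(exp):
            exp_rows.append(summarize(exp["clover"], str(clone), rep, min_cells))
        if len(ctrl):
            ctrl_rows.append(summarize(ctrl["clover"], str(clone), rep, min_cells))
    cols = ["clone_id", "replicate", "n_cells", "mean", "variance", "cv2", "low_n"]
    return (
        pd.DataFrame([vars(s) for s in exp_rows], columns=cols),
        pd.DataFrame([vars(s) for s in ctrl_rows], columns=cols),
    )


def aggregate_replicates(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-clone arithmetic average of mean and CV² across available
    replicates (their count is recorded)."""
    agg = summaries.groupby("clone_id").agg(
        mean_avg=("mean", "mean"),
        cv2_avg=("cv2", "mean"),
        n_replicates=("replicate", "nunique"),
    )
    return agg.reset_index()


def replicate_correlation(
    summaries: pd.DataFrame, value: str = "mean", method: str = "spearman"
) -> pd.DataFrame:
    """Pairwise replicate x replicate rank-correlation matrix of a per-clone
    statistic (``mean`` or ``cv2``) across clones."""
    wide = summaries.pivot(index="clone_id", columns="replicate", values=value)
    reps = list(wide.columns)
    out = pd.DataFrame(np.eye(len(reps)), index=reps, columns=reps)
    for i, a in enumerate(reps):
        for b in reps[i + 1:]:
            pair = wide[[a, b]].dropna()
            if method == "spearman":
                rho = stats.spearmanr(pair[a], pair[b]).statistic
            else:
                rho = stats.pearsonr(pair[a], pair[b]).statistic
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def log10_histograms(
    events: pd.DataFrame, bins: int = 100, value: str = "clover"
) -> pd.DataFrame:
    """Per-clone probability-density histograms of log10 intensity on a shared
    grid (stacked-histogram export)."""
    x = np.log10(events[value].clip(lower=1e-9))
    edges = np.linspace(x.min(), x.max(), bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    rows = {}
    for clone, grp in events.groupby("clone_id"):
        dens, _ = np.histogram(
            np.log10(grp[value].clip(lower=1e-9)), bins=edges, density=True
        )
        rows[clone] = dens
    df = pd.DataFrame.from_dict(rows, orient="index", columns=np.round(centers, 4))
    df.index.name = "clone_id"
    return df


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if (df[EVENT_COLUMNS] < 0).any().any():
        raise ValueError("negative intensities in event table")
    return df
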