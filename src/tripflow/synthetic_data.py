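"""Seeded generator for every input the pipeline consumes, with ground truth.

A :class:`SyntheticConfig` fully determines a founder-cell population: 16-nt
barcodes over {A,T,G} (pairwise Hamming distance > 2), one integration site
per clone on a toy genome, a binned epigenome (TF signal tracks and a state
segmentation), and per-clone lognormal reporter-expression parameters that
are deterministic functions of the clone's chromatin features:

    log10(mean) = a0 + sum_j beta_j z_j + eps
    log10(cv2)  = b0 - s * log10(mean) + sum_j gamma_j z_j + eps'

with s > 0 coupling noise negatively to mean.  Downstream recovery tests can
join every simulated output back to the ground truth by clone id.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .barcode_calling import ReadRecord
from .feature_integration import (
    CHROMHMM_STATES,
    SignalTrack,
    StateSegmentation,
    distance_to_state,
    window_enrichment,
)
from .pool_decoding import (
    CapacityError,
    PoolCountTable,
    PoolingDesign,
    design_capacity,
)

BARCODE_ALPHABET = "ATG"  # error substitutions may still produce any base
_ALL_BASES = "ACGT"


@dataclass
class SyntheticConfig:
    """Everything needed to regenerate one synthetic experiment, seed included."""

    n_clones: int
    barcode_length: int = 16
    n_pools: int = 18
    signature_weight: int = 4
    per_base_error_rate: float = 0.001
    reads_per_barcode: int = 200
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("chr1", 10_000_000),
        ("chr2", 10_000_000),
        ("chr3", 10_000_000),
    )
    n_tf_tracks: int = 5
    track_bin_size: int = 1_000
    n_states: int = 8
    cells_per_clone: int = 50_000
    control_fraction: float = 0.2
    seed: int = 0

    # expression model
    baseline_log10_mean: float = 3.0
    baseline_log10_cv2: float = 2.0
    mean_cv2_coupling: float = 1.0  # s > 0: CV2 falls as mean rises
    n_tf_effects_mean: int = 2
    n_tf_effects_noise: int = 2
    n_state_effects_mean: int = 1
    n_state_effects_noise: int = 1
    effect_size_mean: float = 0.3
    effect_size_noise: float = 0.3
    residual_sd_mean: float = 0.05
    residual_sd_noise: float = 0.05
    # explicit effect overrides (per TF track / per state, on log10 scales)
    tf_effects_mean: tuple[float, ...] | None = None
    tf_effects_noise: tuple[float, ...] | None = None
    state_effects_mean: tuple[float, ...] | None = None
    state_effects_noise: tuple[float, ...] | None = None

    # pool-sequencing nuisances
    pool_background: float = 0.0
    merged_pair_rate: float = 0.0
    double_barcode_rate: float = 0.0
    pool_depth_imbalance: float = 0.0  # sd of lognormal per-pool depth factor

    # integration-site mapping nuisances
    trip_reads_per_barcode: int = 50
    trip_position_jitter: int = 0
    trip_off_target_rate: float = 0.0
    trip_discordant_fraction: float = 0.0

    # flow cytometry
    n_flow_replicates: int = 3
    flow_batch_factors: tuple[float, ...] = (1.0, 1.0, 1.0)
    flow_fsc_coupling: float = 0.0  # >0 makes clover covary with cell size
    irfp_background_ln: tuple[float, float] = (2.0, 0.4)
    irfp_control_ln: tuple[float, float] = (6.0, 0.4)
    control_clover_ln: tuple[float, float] = (5.0, 0.4)

    def __post_init__(self) -> None:
        if self.signature_weight >= self.n_pools:
            raise ValueError("signature_weight must be < n_pools")
        cap = design_capacity(self.n_pools, self.signature_weight)
        if self.n_clones > cap:
            raise CapacityError(
                f"{self.n_clones} clones exceed design capacity {cap}"
            )
        for name in ("n_clones", "barcode_length", "n_pools", "signature_weight",
                     "reads_per_barcode", "n_tf_tracks", "track_bin_size",
                     "n_states", "cells_per_clone", "trip_reads_per_barcode"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.per_base_error_rate < 1:
            raise ValueError("per_base_error_rate must be in [0, 1)")
        if any(length <= 0 for _, length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if len(self.flow_batch_factors) < self.n_flow_replicates:
            raise ValueError("need one batch factor per flow replicate")

    @property
    def clone_ids(self) -> list[str]:
        return [f"clone{i:04d}" for i in range(self.n_clones)]

    @property
    def state_labels(self) -> tuple[str, ...]:
        base = list(CHROMHMM_STATES[: self.n_states])
        base += [f"S{i}" for i in range(len(base), self.n_states)]
        return tuple(base)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "chrom_lengths" in raw:
            raw["chrom_lengths"] = tuple(
                (str(n), int(l)) for n, l in raw["chrom_lengths"]
            )
        for key in ("flow_batch_factors", "tf_effects_mean", "tf_effects_noise",
                    "state_effects_mean", "state_effects_noise"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Generator-side truth retained for recovery testing."""

    barcodes: dict[str, str]                      # clone -> 16-nt sequence
    sites: dict[str, tuple[str, int, str]]        # clone -> (chrom, pos, strand)
    tf_effects_mean: np.ndarray
    tf_effects_noise: np.ndarray
    state_effects_mean: np.ndarray
    state_effects_noise: np.ndarray
    expression: dict[str, tuple[float, float]]    # clone -> lognormal (mu, sigma)
    features: pd.DataFrame = field(repr=False)    # raw clones x features
    log10_mean: dict[str, float] = field(default_factory=dict)
    log10_cv2: dict[str, float] = field(default_factory=dict)

    @property
    def clone_ids(self) -> list[str]:
        return list(self.barcodes)

    @property
    def barcode_to_clone(self) -> dict[str, str]:
        return {b: c for c, b in self.barcodes.items()}

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"clone_id": c, "chrom": ch, "pos": p, "strand": s}
                for c, (ch, p, s) in self.sites.items()
            ]
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "barcodes": self.barcodes,
            "sites": {c: list(s) for c, s in self.sites.items()},
            "tf_effects_mean": self.tf_effects_mean.tolist(),
            "tf_effects_noise": self.tf_effects_noise.tolist(),
            "state_effects_mean": self.state_effects_mean.tolist(),
            "state_effects_noise": self.state_effects_noise.tolist(),
            "expression": {c: list(v) for c, v in self.expression.items()},
            "features": json.loads(self.features.to_json(orient="split")),
            "log10_mean": self.log10_mean,
            "log10_cv2": self.log10_cv2,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        feats = pd.DataFrame(
            raw["features"]["data"],
            index=raw["features"]["index"],
            columns=raw["features"]["columns"],
        )
        feats.index.name = "clone_id"
        return cls(
            barcodes=raw["barcodes"],
            sites={c: (s[0], int(s[1]), s[2]) for c, s in raw["sites"].items()},
            tf_effects_mean=np.asarray(raw["tf_effects_mean"]),
            tf_effects_noise=np.asarray(raw["tf_effects_noise"]),
            state_effects_mean=np.asarray(raw["state_effects_mean"]),
            state_effects_noise=np.asarray(raw["state_effects_noise"]),
            expression={c: (v[0], v[1]) for c, v in raw["expression"].items()},
            features=feats,
            log10_mean=raw["log10_mean"],
            log10_cv2=raw["log10_cv2"],
        )


def _rng(config: SyntheticConfig, key: str) -> np.random.Generator:
    # independent, order-insensitive stream per simulation component
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(key.encode())])
    )


# ---------------------------------------------------------------------------
# Barcodes / sites / epigenome
# ---------------------------------------------------------------------------

def _generate_barcodes(
    n: int, length: int, rng: np.random.Generator, min_distance: int = 3,
    existing: list[str] | None = None,
) -> list[str]:
    """Random {A,T,G} barcodes with pairwise Hamming distance >= min_distance."""
    alphabet = np.frombuffer(BARCODE_ALPHABET.encode(), dtype=np.uint8)
    kept: list[np.ndarray] = [
        np.frombuffer(b.encode(), dtype=np.uint8) for b in (existing or [])
    ]
    out: list[str] = []
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 1000 * (n + 1):
            raise RuntimeError("barcode rejection sampling failed to converge")
        cand = alphabet[rng.integers(0, len(alphabet), size=length)]
        if kept:
            dists = (np.stack(kept) != cand).sum(axis=1)
            if dists.min() < min_distance:
                continue
        kept.append(cand)
        out.append(cand.tobytes().decode())
    return out


def _make_epigenome(
    config: SyntheticConfig,
) -> tuple[list[SignalTrack], StateSegmentation]:
    """Deterministic synthetic epigenome: smooth positive TF tracks and a
    random segmentation tiling every chromosome exactly once."""
    rng = _rng(config, "epigenome")
    lengths = dict(config.chrom_lengths)
    tracks = []
    smooth = max(1, 50_000 // config.track_bin_size)
    kernel = np.ones(smooth) / smooth
    for t in range(config.n_tf_tracks):
        values = {}
        for chrom, length in config.chrom_lengths:
            n_bins = -(-length // config.track_bin_size)
            raw = rng.normal(size=n_bins + smooth)
            sm_vals = np.convolve(raw, kernel, mode="same")[:n_bins]
            values[chrom] = np.exp(sm_vals * 2.0)  # lognormal-ish fold changes
        tracks.append(
            SignalTrack(
                name=f"TF{t:02d}", bin_size=config.track_bin_size,
                values=values, chrom_lengths=lengths,
            )
        )

    labels = config.state_labels
    rows = []
    mean_len = 20_000
    for chrom, length in config.chrom_lengths:
        pos = 0
        while pos < length:
            seg_len = int(min(max(200, rng.exponential(mean_len)), length - pos))
            rows.append(
                {
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + seg_len,
                    "state": labels[rng.integers(0, len(labels))],
                }
            )
            pos += seg_len
    seg = StateSegmentation(intervals=pd.DataFrame(rows), states=labels)
    return tracks, seg


def simulate_epigenome(
    truth: GroundTruth | None, config: SyntheticConfig
) -> tuple[list[SignalTrack], StateSegmentation]:
    """Signal tracks + segmentation; identical to the epigenome the ground
    truth's cached features were computed from (same seed stream)."""
    return _make_epigenome(config)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def _pick_effects(
    n_features: int, n_nonzero: int, size: float, rng: np.random.Generator,
    override: tuple[float, ...] | None,
) -> np.ndarray:
    if override is not None:
        eff = np.asarray(override, dtype=float)
        if len(eff) != n_features:
            raise ValueError("effect override length mismatch")
        return eff
    eff = np.zeros(n_features)
    if n_nonzero > 0:
        idx = rng.choice(n_features, size=min(n_nonzero, n_features), replace=False)
        eff[idx] = size * rng.choice([-1.0, 1.0], size=len(idx))
    return eff


def generate_truth(config: SyntheticConfig) -> GroundTruth:
    """Barcodes, sites, chromatin features and expression parameters.

    Expression: target mean M and cv2 C on log10 scales (see module
    docstring) are converted to natural-log lognormal parameters via
    sigma = sqrt(ln(1 + C)), mu = ln(M) - sigma^2 / 2.
    """
    rng = _rng(config, "truth")
    clones = config.clone_ids
    barcodes = dict(
        zip(clones, _generate_barcodes(config.n_clones, config.barcode_length, rng))
    )

    chrom_names = [c for c, _ in config.chrom_lengths]
    chrom_len = dict(config.chrom_lengths)
    sites = {}
    for c in clones:
        chrom = chrom_names[rng.integers(0, len(chrom_names))]
        pos = int(rng.integers(0, chrom_len[chrom]))
        strand = "+" if rng.random() < 0.5 else "-"
        sites[c] = (chrom, pos, strand)

    tracks, seg = _make_epigenome(config)
    feats = {}
    for c in clones:
        chrom, pos, _ = sites[c]
        row = {
            f"enr_{t.name}": window_enrichment(t, chrom, pos, 50_000) for t in tracks
        }
        row.update(
            {
                f"dist_{s}": distance_to_state(seg, chrom, pos, s)
                for s in seg.states
            }
        )
        feats[c] = row
    features = pd.DataFrame.from_dict(feats, orient="index").loc[clones]
    features.index.name = "clone_id"

    # standardized features drive the effects; all-NaN/constant columns -> 0
    z = features.apply(
        lambda col: (col - col.mean()) / col.std(ddof=1)
        if col.std(ddof=1) > 0
        else col * 0.0
    ).fillna(0.0)
    z_tf = z[[f"enr_{t.name}" for t in tracks]].to_numpy()
    z_state = z[[f"dist_{s}" for s in seg.states]].to_numpy()

    beta_tf = _pick_effects(
        config.n_tf_tracks, config.n_tf_effects_mean, config.effect_size_mean,
        rng, config.tf_effects_mean,
    )
    gamma_tf = _pick_effects(
        config.n_tf_tracks, config.n_tf_effects_noise, config.effect_size_noise,
        rng, config.tf_effects_noise,
    )
    beta_state = _pick_effects(
        config.n_states, config.n_state_effects_mean, config.effect_size_mean,
        rng, config.state_effects_mean,
    )
    gamma_state = _pick_effects(
        config.n_states, config.n_state_effects_noise, config.effect_size_noise,
        rng, config.state_effects_noise,
    )

    eps = rng.normal(0, config.residual_sd_mean, config.n_clones)
    eps2 = rng.normal(0, config.residual_sd_noise, config.n_clones)
    log10_mean = (
        config.baseline_log10_mean + z_tf @ beta_tf + z_state @ beta_state + eps
    )
    log10_cv2 = (
        config.baseline_log10_cv2
        - config.mean_cv2_coupling * log10_mean
        + z_tf @ gamma_tf
        + z_state @ gamma_state
        + eps2
    )
    log10_mean = np.clip(log10_mean, 0.0, 6.0)
    log10_cv2 = np.clip(log10_cv2, -3.0, 1.9)

    expression = {}
    for i, c in enumerate(clones):
        cv2 = 10.0 ** log10_cv2[i]
        sigma = float(np.sqrt(np.log1p(cv2)))
        mu = float(np.log(10.0 ** log10_mean[i]) - sigma**2 / 2)
        expression[c] = (mu, sigma)

    return GroundTruth(
        barcodes=barcodes,
        sites=sites,
        tf_effects_mean=beta_tf,
        tf_effects_noise=gamma_tf,
        state_effects_mean=beta_state,
        state_effects_noise=gamma_state,
        expression=expression,
        features=features,
        log10_mean={c: float(log10_mean[i]) for i, c in enumerate(clones)},
        log10_cv2={c: float(log10_cv2[i]) for i, c in enumerate(clones)},
    )


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_barcode_reads(
    truth: GroundTruth, config: SyntheticConfig
) -> list[ReadRecord]:
    """~reads_per_barcode copies of each true barcode with independent
    per-base substitution errors; qualities encode the error rate."""
    rng = _rng(config, "barcode_reads")
    e = config.per_base_error_rate
    q = 40 if e == 0 else int(np.clip(round(-10 * np.log10(e)), 2, 40))
    length = config.barcode_length

    seqs = list(truth.barcodes.values())
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), length)
    reps = np.repeat(np.arange(len(seqs)), config.reads_per_barcode)
    reads = mat[reps].copy()
    if e > 0:
        mask = rng.random(reads.shape) < e
        # substitute with one of the three other bases, uniformly
        bases = np.frombuffer(_ALL_BASES.encode(), dtype=np.uint8)
        idx = np.searchsorted(bases, reads[mask])
        shift = rng.integers(1, 4, size=mask.sum())
        reads[mask] = bases[(idx + shift) % 4]
    qual = tuple([q] * length)
    return [
        ReadRecord(sequence=row.tobytes().decode(), qualities=qual, name=f"read{i}")
        for i, row in enumerate(reads)
    ]


# ---------------------------------------------------------------------------
# Pool counts
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPools:
    table: PoolCountTable
    merged_pairs: list[tuple[str, str, str]]  # (barcode, clone_a, clone_b)
    double_barcodes: dict[str, str]           # clone -> extra barcode


def simulate_pool_counts(
    truth: GroundTruth, design: PoolingDesign, config: SyntheticConfig
) -> SimulatedPools:
    """Multinomial barcode x pool counts concentrated in signature pools.

    ``pool_background`` of each barcode's reads is spread uniformly over all
    pools.  ``merged_pair_rate`` injects barcodes read out over the union of
    two clones' signatures (sister-cell merges; the partner clone's own
    barcode disappears).  ``double_barcode_rate`` injects clones carrying a
    second barcode with an identical signature.
    """
    rng = _rng(config, "pool_counts")
    clones = list(design.assignments)
    n_pools = design.n_pools

    n_merged = int(round(config.merged_pair_rate * len(clones)))
    n_double = int(round(config.double_barcode_rate * len(clones)))
    special = rng.choice(
        len(clones), size=min(len(clones), 2 * n_merged + n_double), replace=False
    )
    merged_a = [clones[i] for i in special[:n_merged]]
    merged_b = [clones[i] for i in special[n_merged: 2 * n_merged]]
    doubles = [clones[i] for i in special[2 * n_merged: 2 * n_merged + n_double]]

    extra_barcodes = _generate_barcodes(
        len(doubles), config.barcode_length, rng,
        existing=list(truth.barcodes.values()),
    )
    double_map = dict(zip(doubles, extra_barcodes))
    merged_partner = dict(zip(merged_a, merged_b))
    dropped = set(merged_b)

    depth_factor = (
        np.exp(rng.normal(0, config.pool_depth_imbalance, n_pools))
        if config.pool_depth_imbalance > 0
        else np.ones(n_pools)
    )

    def _row(signature: frozenset[int], total: int) -> np.ndarray:
        p = np.full(n_pools, config.pool_background / n_pools)
        members = sorted(signature)
        p[members] += (1 - config.pool_background) / len(members)
        p = p * depth_factor
        return rng.multinomial(total, p / p.sum())

    rows: dict[str, np.ndarray] = {}
    merged_log: list[tuple[str, str, str]] = []
    for clone in clones:
        if clone in dropped:
            continue
        barcode = truth.barcodes[clone]
        sig = design.assignments[clone]
        if clone in merged_partner:
            partner = merged_partner[clone]
            union = sig | design.assignments[partner]
            rows[barcode] = _row(union, 2 * config.reads_per_barcode)
            merged_log.append((barcode, clone, partner))
        else:
            rows[barcode] = _row(sig, config.reads_per_barcode)
        if clone in double_map:
            rows[double_map[clone]] = _row(sig, config.reads_per_barcode)

    df = pd.DataFrame.from_dict(rows, orient="index", columns=range(n_pools))
    df.index.name = "barcode"
    return SimulatedPools(
        table=PoolCountTable(counts=df),
        merged_pairs=merged_log,
        double_barcodes=double_map,
    )


# ---------------------------------------------------------------------------
# Integration-site reads
# ---------------------------------------------------------------------------

def simulate_trip_reads(truth: GroundTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Mapped-read table (barcode, chrom, pos, strand, replicate in {1,2}).

    Reads cluster at each barcode's true site; ``trip_off_target_rate``
    scatters single reads uniformly, and a ``trip_discordant_fraction`` of
    barcodes has its replicate-2 reads moved to a different random site.
    """
    rng = _rng(config, "trip_reads")
    chrom_names = [c for c, _ in config.chrom_lengths]
    chrom_len = dict(config.chrom_lengths)
    clones = truth.clone_ids
    n_disc = int(round(config.trip_discordant_fraction * len(clones)))
    discordant = set(
        clones[i] for i in rng.choice(len(clones), size=n_disc, replace=False)
    )

    def _random_site() -> tuple[str, int, str]:
        chrom = chrom_names[rng.integers(0, len(chrom_names))]
        return (
            chrom,
            int(rng.integers(0, chrom_len[chrom])),
            "+" if rng.random() < 0.5 else "-",
        )

    rows = []
    for clone in clones:
        barcode = truth.barcodes[clone]
        true_site = truth.sites[clone]
        for rep in (1, 2):
            site = true_site
            if rep == 2 and clone in discordant:
                site = _random_site()
            for _ in range(config.trip_reads_per_barcode):
                if config.trip_off_target_rate > 0 and rng.random() < config.trip_off_target_rate:
                    chrom, pos, strand = _random_site()
                else:
                    chrom, pos, strand = site
                    if config.trip_position_jitter > 0:
                        pos = int(
                            np.clip(
                                pos + rng.integers(
                                    -config.trip_position_jitter,
                                    config.trip_position_jitter + 1,
                                ),
                                0, chrom_len[chrom] - 1,
                            )
                        )
                rows.append(
                    {
                        "barcode": barcode, "chrom": chrom, "pos": pos,
                        "strand": strand, "replicate": rep,
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["discordant_clones"] = sorted(discordant)
    return out


# ---------------------------------------------------------------------------
# Flow cytometry
# ---------------------------------------------------------------------------

def simulate_flow_events(truth: GroundTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Per-cell event table (clone_id, replicate, fsc, ssc, clover, irfp,
    is_control) for ``n_flow_replicates`` replicates of every clone.

    Experimental cells draw Clover from the clone's lognormal; co-cultured
    control cells draw Clover from one shared lognormal and sit high in IRFP.
    FSC/SSC come from a common correlated bivariate normal independent of the
    clone; an optional multiplicative batch factor scales Clover per
    replicate, and ``flow_fsc_coupling`` > 0 makes Clover covary with FSC.
    """
    rng = _rng(config, "flow")
    n = config.cells_per_clone
    n_ctrl = int(round(config.control_fraction * n))
    n_exp = n - n_ctrl
    frames = []
    for clone in truth.clone_ids:
        mu, sigma = truth.expression[clone]
        for rep in range(1, config.n_flow_replicates + 1):
            batch = config.flow_batch_factors[rep - 1]
            fsc = rng.normal(100_000, 15_000, n).clip(min=1.0)
            ssc = (0.6 * fsc + rng.normal(0, 10_000, n)).clip(min=1.0)
            clover = np.empty(n)
            irfp = np.empty(n)
            clover[:n_exp] = rng.lognormal(mu, sigma, n_exp)
            irfp[:n_exp] = rng.lognormal(*config.irfp_background_ln, n_exp)
            clover[n_exp:] = rng.lognormal(*config.control_clover_ln, n_ctrl)
            irfp[n_exp:] = rng.lognormal(*config.irfp_control_ln, n_ctrl)
            clover = clover * batch
            if config.flow_fsc_coupling > 0:
                clover = clover * (fsc / 100_000) ** config.flow_fsc_coupling
            frames.append(
                pd.DataFrame(
                    {
                        "clone_id": clone,
                        "replicate": rep,
                        "fsc": fsc,
                        "ssc": ssc,
                        "clover": clover,
                        "irfp": irfp,
                        "is_control": np.arange(n) >= n_exp,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Screening benchmark (feature matrix with planted effects)
# ---------------------------------------------------------------------------

def simulate_screen_dataset(
    n_obs: int = 90,
    n_features: int = 200,
    n_effects: int = 5,
    effect_size: float = 0.5,
    noise_sd: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Gaussian feature matrix with ``n_effects`` planted linear effects —
    the benchmark for screen + regression recovery.  Returns (X, y, planted
    feature names)."""
    rng = np.random.default_rng(seed)
    names = [f"f{i:03d}" for i in range(n_features)]
    X = pd.DataFrame(
        rng.normal(size=(n_obs, n_features)), columns=names,
        index=[f"clone{i:04d}" for i in range(n_obs)],
    )
    planted = sorted(rng.choice(n_features, size=n_effects, replace=False))
    beta = np.zeros(n_features)
    beta[planted] = effect_size * rng.choice([-1.0, 1.0], size=n_effects)
    y = pd.Series(
        X.to_numpy() @ beta + rng.normal(0, noise_sd, n_obs),
        index=X.index, name="response",
    )
    return X, y, [names[i] for i in planted]


# ---------------------------------------------------------------------------
# Writing a full dataset to disk
# ---------------------------------------------------------------------------

def write_dataset(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input under ``out_dir`` and return the paths."""
    from .barcode_calling import write_fastq
    from .pool_decoding import make_design
    from . import trip_mapping

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    truth = generate_truth(config)
    paths["truth"] = out / "truth.json"
    truth.to_json(paths["truth"])

    reads = simulate_barcode_reads(truth, config)
    paths["reads"] = out / "barcode_reads.fastq"
    write_fastq(reads, paths["reads"])

    # balanced scheme keeps per-pool depths comparable, which the row-relative
    # positive-pool threshold relies on
    design = make_design(
        config.n_clones, config.n_pools, config.signature_weight,
        scheme="balanced", clone_ids=config.clone_ids,
    )
    paths["design"] = out / "design.tsv"
    design.to_tsv(paths["design"])

    pools = simulate_pool_counts(truth, design, config)
    paths["pool_counts"] = out / "pool_counts.tsv"
    pools.table.to_tsv(paths["pool_counts"])

    trip = simulate_trip_reads(truth, config)
    for rep in (1, 2):
        paths[f"trip_rep{rep}"] = out / f"trip_rep{rep}.tsv"
        trip_mapping.write_table(trip[trip["replicate"] == rep], paths[f"trip_rep{rep}"])

    flow = simulate_flow_events(truth, config)
    paths["flow_events"] = out / "flow_events.csv"
    flow.drop(columns="is_control").to_csv(paths["flow_events"], index=False)

    tracks, seg = simulate_epigenome(truth, config)
    track_dir = out / "tracks"
    track_dir.mkdir(exist_ok=True)
    for t in tracks:
        t.to_bedgraph(track_dir / f"{t.name}.bedGraph")
    paths["tracks"] = track_dir
    paths["states"] = out / "states.bed"
    seg.to_bed(paths["states"])

    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=list)
    return paths
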