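"""Synthetic single-cell WGA cohorts with known ground truth.

Real single-nucleus sequencing of amplified genomes shows, per chemistry,
a characteristic amount of bin-to-bin multiplicative noise, locus-specific
amplification bias recurring across cells, a mild coverage-vs-GC trend,
and locus dropout. The generator reproduces that structure on a synthetic
genome: per-bin expected depth is

    mean_reads_per_bin x (CN/2) x GC-factor x exp(shared artifact)
                       x lognormal bin noise,

optionally zeroed by dropout, and observed counts are Poisson draws around
it. Cells of the same individual share the artifact tracks (with per-cell
loadings), which is what PCA denoising exploits downstream. Default noise
scales per chemistry are calibrated so cohort mean MAD lands near the
published per-method values (PicoPLEX ~0.15, PTA ~0.24, dMDA ~0.57).

Ground-truth CNVs (private per-cell events from a menu, plus optional
shared "artifact" events spanning many cells or individuals) are embedded
by scaling expected depth by CN/2 over their span and returned alongside
the counts for recovery scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import child_rng, is_autosome
from .chimera import PairRecord
from .coverage import BinScheme, BIN_COLUMNS

CATEGORIES = ("inward", "outward", "interchrom", "other")


@dataclass
class WgaProfile:
    """Noise characteristics of one amplification chemistry.

    bin_noise_sd: SD of the lognormal multiplicative amplification noise at
        the noise_unit_bp scale (the granularity of amplification bias).
        Bins larger than one noise unit average several independent draws,
        so per-bin noise shrinks with bin size — the reason large bins
        rescue noisy chemistries.
    artifact_amplitude: total SD of the shared (per-individual) artifact
        component on the log-depth scale.
    n_artifact_components: number of shared artifact tracks.
    gc_slope: log-linear coverage response to GC content around GC 0.42.
    dropout_rate: fraction of the genome lost to locus dropout. Dropout
        acts on ~dropout_unit_bp stretches (the scale of amplification
        fragments), so small bins go to zero outright while large bins
        lose a fraction of their depth.
    """

    name: str
    bin_noise_sd: float
    artifact_amplitude: float = 0.0
    n_artifact_components: int = 0
    gc_slope: float = 0.0
    dropout_rate: float = 0.0
    dropout_unit_bp: int = 250_000
    noise_unit_bp: int = 500_000

    def __post_init__(self):
        if self.bin_noise_sd < 0:
            raise ValueError("bin_noise_sd must be >= 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_artifact_components < 0:
            raise ValueError("n_artifact_components must be >= 0")


#: per-chemistry defaults; bin_noise_sd values are calibrated so that the
#: default cohort (500 reads/bin) reproduces the published mean MAD per method
DEFAULT_PROFILES: dict[str, WgaProfile] = {
    "picoplex": WgaProfile("picoplex", bin_noise_sd=0.099,
                           artifact_amplitude=0.05, n_artifact_components=2,
                           gc_slope=-0.3, dropout_rate=0.0),
    "pta": WgaProfile("pta", bin_noise_sd=0.160,
                      artifact_amplitude=0.08, n_artifact_components=3,
                      gc_slope=-1.2, dropout_rate=0.01),
    "dmda": WgaProfile("dmda", bin_noise_sd=0.378,
                       artifact_amplitude=0.20, n_artifact_components=4,
                       gc_slope=-1.5, dropout_rate=0.06),
}

#: per-chemistry discordant read-pair mixes. Orderings follow the observed
#: qualitative pattern: outward (tandem-duplication-like) pairs are most
#: frequent in PicoPLEX and least in PTA; inter-chromosomal pairs peak in
#: PTA and are rarest in dMDA; same-strand ("other", inversion-like) pairs
#: peak in PTA, are common in dMDA and nearly absent in PicoPLEX.
CHIMERA_MIXES: dict[str, dict[str, float]] = {
    "picoplex": {"inward": 0.900, "outward": 0.080, "interchrom": 0.018,
                 "other": 0.002},
    "pta": {"inward": 0.925, "outward": 0.010, "interchrom": 0.035,
            "other": 0.030},
    "dmda": {"inward": 0.940, "outward": 0.030, "interchrom": 0.010,
             "other": 0.020},
}


@dataclass
class TruthCnv:
    """A ground-truth copy-number event planted in one cell."""

    cell_id: str
    chrom: str
    start: int
    end: int
    cn: int
    kind: str = "private"  # 'private' or 'artifact'

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("TruthCnv needs end > start")
        if self.cn == 2 or self.cn < 0:
            raise ValueError("TruthCnv copy number must be non-negative and != 2")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class ArtifactCnv:
    """A recurrent artifact event shared by many cells (and optionally
    individuals), used to exercise the multi-cell artifact filter."""

    chrom: str
    start: int
    end: int
    cn: int
    carrier_fraction: float = 0.6
    individuals: list[str] | None = None  # None -> all individuals


@dataclass
class CohortSpec:
    """Study design for one synthetic cohort.

    ``cells`` lists (individual_id, method, n_cells) groups; ``cnv_menu``
    lists (size_bp, cn, frequency) private-event classes, where frequency is
    the per-cell probability of carrying one such event.
    """

    cells: list[tuple[str, str, int]]
    genome: list[tuple[str, int]]
    bin_size: int = 500_000
    mean_reads_per_bin: float = 500.0
    cnv_menu: list[tuple[int, int, float]] = field(default_factory=list)
    artifact_cnvs: list[ArtifactCnv] = field(default_factory=list)
    shared_artifact_seed: int = 0
    rng_seed: int = 1
    sampling: str = "poisson"  # 'poisson' or 'expected' (noise-free counts)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.mean_reads_per_bin <= 0:
            raise ValueError("mean_reads_per_bin must be positive")
        if self.sampling not in ("poisson", "expected"):
            raise ValueError(f"unknown sampling mode: {self.sampling!r}")

    def cell_ids(self) -> list[tuple[str, str, str]]:
        """Flat list of (cell_id, individual_id, method)."""
        out = []
        for individual, method, n in self.cells:
            for i in range(n):
                out.append((f"{individual}_{method}_{i:02d}", individual, method))
        return out


# ---------------------------------------------------------------------------
# cohort simulation


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = np.concatenate([x[window - 1:0:-1], x, x[-2:-window - 1:-1]])
    return np.convolve(pad, kernel, mode="same")[window - 1:window - 1 + len(x)]


def _make_bins(spec: CohortSpec) -> BinScheme:
    """Fixed bins over the synthetic genome with a smooth GC landscape."""
    rng = child_rng(spec.shared_artifact_seed, "gc")
    rows = []
    for chrom, length in spec.genome:
        starts = np.arange(0, length, spec.bin_size)
        ends = np.minimum(starts + spec.bin_size, length)
        gc = 0.42 + 0.06 * _smooth(rng.standard_normal(len(starts)), 9)
        gc = np.clip(gc, 0.28, 0.58)
        for s, e, g in zip(starts, ends, gc):
            rows.append((chrom, int(s), int(e), float(g), 1.0))
    return BinScheme(pd.DataFrame(rows, columns=BIN_COLUMNS),
                     f"{spec.bin_size // 1000} kb")


def _artifact_tracks(spec: CohortSpec, individual: str, k: int,
                     n_bins: int) -> np.ndarray:
    """k shared tracks (unit SD each) for one individual: half bin-level
    recurrent bias, half low-frequency random walk."""
    if k == 0:
        return np.zeros((0, n_bins))
    rng = child_rng(spec.shared_artifact_seed, "tracks", individual)
    tracks = np.empty((k, n_bins))
    for t in range(k):
        white = rng.standard_normal(n_bins)
        walk = np.cumsum(rng.standard_normal(n_bins))
        walk = (walk - walk.mean()) / max(walk.std(), 1e-9)
        tracks[t] = math.sqrt(0.5) * white + math.sqrt(0.5) * walk
    return tracks


def _overlap_frac(bin_start, bin_end, ev_start, ev_end) -> np.ndarray:
    ov = np.clip(np.minimum(bin_end, ev_end) - np.maximum(bin_start, ev_start),
                 0, None)
    return ov / (bin_end - bin_start)


def _cn_factor(bins: BinScheme, events: list[TruthCnv]) -> np.ndarray:
    cn = np.full(bins.n_bins, 2.0)
    starts = bins.df["start"].to_numpy()
    ends = bins.df["end"].to_numpy()
    chroms = bins.chrom_labels
    for ev in events:
        on = chroms == ev.chrom
        cn[on] += (ev.cn - 2) * _overlap_frac(starts[on], ends[on],
                                              ev.start, ev.end)
    return np.clip(cn, 0.0, None) / 2.0


def _draw_private_events(spec: CohortSpec, cell_id: str, bins: BinScheme,
                         rng: np.random.Generator,
                         occupied: list[TruthCnv] = ()) -> list[TruthCnv]:
    autosomes = [(c, ln) for c, ln in spec.genome if is_autosome(c)]
    blocked: list[TruthCnv] = list(occupied)
    events: list[TruthCnv] = []
    for size, cn, freq in spec.cnv_menu:
        if rng.random() >= freq:
            continue
        if not np.isscalar(size):  # (lo, hi) range: somatic events vary
            lo, hi = size
            size = int(rng.integers(int(lo), int(hi) + 1))
        fits = [(c, ln) for c, ln in autosomes if ln >= size]
        if not fits:
            raise ValueError(f"no autosome can hold a {size} bp event")
        lengths = np.array([ln for _, ln in fits], dtype=float)
        for _ in range(20):  # rejection-sample a non-overlapping placement
            ci = rng.choice(len(fits), p=lengths / lengths.sum())
            chrom, ln = fits[ci]
            start = int(rng.integers(0, ln - size + 1))
            end = start + size
            clash = any(ev.chrom == chrom and ev.start < end and start < ev.end
                        for ev in blocked)
            if not clash:
                ev = TruthCnv(cell_id, chrom, start, end, cn)
                events.append(ev)
                blocked.append(ev)
                break
    return events


def simulate_cohort(spec: CohortSpec,
                    profiles: dict[str, WgaProfile] | None = None
                    ) -> tuple[pd.DataFrame, list[TruthCnv], BinScheme]:
    """Generate raw bin counts for a cohort plus its ground-truth events.

    Returns (counts, truths, bins) where ``counts`` is a bins x cells integer
    DataFrame (columns = cell ids). Reproducible bit-for-bit given the spec's
    seeds: each cell draws from its own seed stream keyed by cell id, so
    output does not depend on processing order.
    """
    profiles = DEFAULT_PROFILES if profiles is None else profiles
    roster = spec.cell_ids()
    for _, _, method in roster:
        if method not in profiles:
            raise ValueError(f"no WGA profile for method {method!r}")

    bins = _make_bins(spec)
    gc = bins.df["gc"].to_numpy()
    n_bins = bins.n_bins

    # shared artifact tracks per individual (as many as any method needs)
    per_ind_k: dict[str, int] = {}
    for _, individual, method in roster:
        k = profiles[method].n_artifact_components
        per_ind_k[individual] = max(per_ind_k.get(individual, 0), k)
    tracks = {ind: _artifact_tracks(spec, ind, k, n_bins)
              for ind, k in per_ind_k.items()}

    # carriers of shared artifact events, deterministic per individual
    ind_cells: dict[str, list[str]] = {}
    for cell_id, individual, _ in roster:
        ind_cells.setdefault(individual, []).append(cell_id)
    artifact_truths: dict[str, list[TruthCnv]] = {c: [] for c, _, _ in roster}
    for art in spec.artifact_cnvs:
        targets = art.individuals or list(ind_cells)
        for ind in targets:
            n_carry = math.ceil(art.carrier_fraction * len(ind_cells[ind]))
            for cell_id in ind_cells[ind][:n_carry]:
                artifact_truths[cell_id].append(
                    TruthCnv(cell_id, art.chrom, art.start, art.end, art.cn,
                             kind="artifact"))

    counts = {}
    truths: list[TruthCnv] = []
    for cell_id, individual, method in roster:
        prof = profiles[method]
        rng = child_rng(spec.rng_seed, "cell", cell_id)
        events = _draw_private_events(spec, cell_id, bins, rng,
                                      occupied=artifact_truths[cell_id])
        events += artifact_truths[cell_id]
        truths.extend(events)

        expected = spec.mean_reads_per_bin * _cn_factor(bins, events)
        expected *= np.clip(np.exp(prof.gc_slope * (gc - 0.42)), 0.2, 3.0)
        k = prof.n_artifact_components
        if k > 0 and prof.artifact_amplitude > 0:
            w = rng.normal(1.0, 0.3, size=k)
            shared = (w @ tracks[individual][:k]) / math.sqrt(k)
            expected *= np.exp(prof.artifact_amplitude * shared)
        if prof.bin_noise_sd > 0:
            n_sub = max(1, round(spec.bin_size / prof.noise_unit_bp))
            z = rng.standard_normal((n_bins, n_sub))
            expected *= np.exp(prof.bin_noise_sd * z
                               - 0.5 * prof.bin_noise_sd ** 2).mean(axis=1)
        if prof.dropout_rate > 0:
            n_units = max(1, round(spec.bin_size / prof.dropout_unit_bp))
            kept = rng.binomial(n_units, 1.0 - prof.dropout_rate, n_bins)
            expected *= kept / n_units
        if spec.sampling == "poisson":
            counts[cell_id] = rng.poisson(expected)
        else:
            counts[cell_id] = np.round(expected).astype(np.int64)

    return pd.DataFrame(counts, dtype=np.int64), truths, bins


# ---------------------------------------------------------------------------
# read-pair simulation

_DEFAULT_PAIR_GENOME = (("chr1", 100_000_000), ("chr2", 80_000_000))


def simulate_pairs(n_pairs: int, mix: dict[str, float], rng_seed: int = 1,
                   genome=_DEFAULT_PAIR_GENOME) -> list[PairRecord]:
    """Read pairs with the requested orientation-category mix.

    Categories: inward (concordant), outward (tandem-duplication-like),
    interchrom (translocation-like), other (same-strand, inversion-like).
    Each record's geometry is generated so the classifier recovers its
    category; mate order is randomized.
    """
    probs = np.zeros(len(CATEGORIES))
    for key, val in mix.items():
        if key not in CATEGORIES:
            raise ValueError(f"unknown pair category {key!r}")
        if val < 0:
            raise ValueError("mix proportions must be non-negative")
        probs[CATEGORIES.index(key)] = val
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("mix proportions must sum to 1")

    rng = child_rng(rng_seed, "pairs")
    chroms = [c for c, _ in genome]
    lengths = {c: ln for c, ln in genome}
    records = []
    for _ in range(int(n_pairs)):
        cat = CATEGORIES[rng.choice(len(CATEGORIES), p=probs)]
        c1 = chroms[rng.integers(len(chroms))]
        if cat == "interchrom":
            c2 = chroms[(chroms.index(c1) + 1 + rng.integers(len(chroms) - 1))
                        % len(chroms)]
            p1 = int(rng.integers(0, lengths[c1]))
            p2 = int(rng.integers(0, lengths[c2]))
            s1, s2 = rng.choice(["+", "-"], size=2)
            rec = PairRecord(c1, p1, s1, c2, p2, s2)
        else:
            gap = int(rng.integers(200, 600)) if cat == "inward" \
                else int(rng.integers(2_000, 500_000))
            p1 = int(rng.integers(0, lengths[c1] - gap))
            p2 = p1 + gap
            if cat == "inward":
                s1, s2 = "+", "-"
            elif cat == "outward":
                s1, s2 = "-", "+"
            else:  # other: same strand
                s1 = s2 = str(rng.choice(["+", "-"]))
            rec = PairRecord(c1, p1, s1, c1, p2, s2)
        if rng.random() < 0.5:  # mate order carries no information
            rec = PairRecord(rec.chrom2, rec.pos2, rec.strand2,
                             rec.chrom1, rec.pos1, rec.strand1,
                             rec.mq2, rec.mq1)
        records.append(rec)
    return records


def simulate_method_pairs(method: str, n_pairs: int,
                          rng_seed: int = 1) -> list[PairRecord]:
    """Read pairs with the default discordance mix of one chemistry."""
    if method not in CHIMERA_MIXES:
        raise ValueError(f"no chimera mix for method {method!r}")
    return simulate_pairs(n_pairs, CHIMERA_MIXES[method],
                          rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# recovery scoring against ground truth


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def score_recovery(calls: pd.DataFrame, truths: list[TruthCnv],
                   min_overlap: float = 0.5) -> dict[str, float]:
    """Recall/precision of CNV calls against planted private events.

    A truth event is recovered when a call in the same cell, of the matching
    direction, overlaps at least ``min_overlap`` of the truth span; a call is
    a true positive when it overlaps at least ``min_overlap`` of its own span
    with such a truth event.
    """
    private = [t for t in truths if t.kind == "private"]
    n_found = 0
    for t in private:
        t_type = "loss" if t.cn < 2 else "gain"
        sub = calls[(calls["cell_id"] == t.cell_id) & (calls["type"] == t_type)
                    & (calls["chrom"] == t.chrom)]
        got = any(_overlap(t.start, t.end, c.start, c.end)
                  >= min_overlap * t.span for c in sub.itertuples())
        n_found += got
    n_tp = 0
    for c in calls.itertuples():
        matches = [t for t in private
                   if t.cell_id == c.cell_id and t.chrom == c.chrom
                   and ("loss" if t.cn < 2 else "gain") == c.type
                   and _overlap(t.start, t.end, c.start, c.end)
                   >= min_overlap * (c.end - c.start)]
        n_tp += bool(matches)
    recall = n_found / len(private) if private else float("nan")
    precision = n_tp / len(calls) if len(calls) else float("nan")
    return {"recall": recall, "precision": precision,
            "n_truth": len(private), "n_calls": int(len(calls))}


def truth_to_bed(truths: list[TruthCnv]) -> pd.DataFrame:
    return pd.DataFrame([(t.chrom, t.start, t.end, t.cell_id, t.cn, t.kind)
                         for t in truths],
                        columns=["chrom", "start", "end", "cell_id", "cn",
                                 "kind"])
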