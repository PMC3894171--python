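"""TSS-anchored promoter scanning with a permutation null.

Each promoter window (default -50..+150 around the TSS, sense strand only)
is scanned with a PWM; every k-mer score is converted to an empirical
p-value against a null of scores from composition-permuted promoter
sequence, and to a similarity index -log10(p).  Group-level statistics
(paused vs non-paused genes) compare the per-gene maximum similarity index
inside the promoter-proximal pause region (+10..+30 by default) with a
two-sample Kolmogorov-Smirnov test and Welch's unequal-variance t-test.

Coordinate convention: offset 0 is the first transcribed base (the TSS);
a k-mer is assigned the offset of its 5'-most base, so a window spanning
[-50, +150] yields scores at offsets -50 .. +(150 - k + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .motif import PositionWeightMatrix, encode

logger = logging.getLogger(__name__)

WINDOW_START = -50
WINDOW_END = 150  # inclusive
PAUSE_REGION = (10, 30)

__all__ = [
    "PromoterWindow",
    "NullScoreDistribution",
    "SimilarityTrack",
    "PauseComparisonResult",
    "build_null",
    "empirical_pvalue",
    "scan_windows",
    "best_match_per_gene",
    "average_profile",
    "compare_groups",
    "heatmap_matrix",
    "positional_boxplot_stats",
    "PromoterScanModel",
    "PromoterScanResults",
]


@dataclass(frozen=True)
class PromoterWindow:
    """A promoter sequence anchored at the TSS on the gene's sense strand."""

    gene_id: str
    sequence: str
    group: str | None = None  # "paused" / "non_paused" / None
    start_offset: int = WINDOW_START

    @property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)

    def offset_of(self, index: int) -> int:
        return self.start_offset + index

    def index_of(self, offset: int) -> int:
        return offset - self.start_offset


@dataclass(frozen=True)
class NullScoreDistribution:
    """Sorted null PWM scores from permuted promoter sequence.

    ``scheme`` records how the null k-mers were drawn:

    - ``"window_permute"`` (default): pick a window uniformly, permute its
      letters uniformly at random (preserving that window's base
      composition), and read the k-mer at a uniform offset.
    - ``"kmer_shuffle"``: pick a window and offset uniformly, and shuffle
      the letters of that single observed k-mer.
    """

    scores: np.ndarray  # sorted ascending
    scheme: str
    seed: int

    @property
    def n(self) -> int:
        return self.scores.size


def empirical_pvalue(score: float, null: NullScoreDistribution) -> float:
    """Add-one empirical p-value: (1 + #{null >= score}) / (N + 1).

    The add-one correction keeps p > 0 so -log10(p) is finite; p is capped
    at 1 from above by construction.
    """
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    n_ge = null.n - int(np.searchsorted(null.scores, score, side="left"))
    return (1 + n_ge) / (null.n + 1)


def _empirical_pvalues(scores: np.ndarray, null: NullScoreDistribution) -> np.ndarray:
    """Vectorized add-one empirical p-values; NaN scores stay NaN."""
    out = np.full(scores.shape, np.nan)
    ok = np.isfinite(scores)
    n_ge = null.n - np.searchsorted(null.scores, scores[ok], side="left")
    out[ok] = (1 + n_ge) / (null.n + 1)
    return out


def _window_kmer_scores(codes: np.ndarray, pwm: PositionWeightMatrix) -> np.ndarray:
    """Scores for every k-mer of an encoded window; NaN where ambiguous."""
    k = pwm.k
    if codes.size < k:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = np.all(windows >= 0, axis=1)
    scores = np.full(windows.shape[0], np.nan)
    if valid.any():
        vw = windows[valid]
        scores[valid] = pwm.scores[np.arange(k)[None, :], vw].sum(axis=1)
    return scores


def build_null(
    windows: list[PromoterWindow],
    pwm: PositionWeightMatrix,
    n: int = 100_000,
    seed: int = 0,
    scheme: str = "window_permute",
) -> NullScoreDistribution:
    """Draw ``n`` null k-mer scores from permuted promoter sequence.

    Ambiguous bases are excluded: draws whose k-mer would contain a
    non-ACGT code are rejected and redrawn.
    """
    if len(windows) == 0:
        raise ValueError("cannot build a null from an empty window set")
    if n < 1000:
        raise ValueError("null size must be >= 1000")
    if scheme not in ("window_permute", "kmer_shuffle"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    k = pwm.k
    rng = np.random.default_rng(seed)
    encoded = [w.codes for w in windows if len(w.sequence) >= k]
    if not encoded:
        raise ValueError("no window is at least k bases long")
    lengths = np.array([c.size for c in encoded])

    collected: list[np.ndarray] = []
    remaining = n
    while remaining > 0:
        chunk = min(max(remaining, 1024), 50_000)
        widx = rng.integers(0, len(encoded), size=chunk)
        kmers = np.empty((chunk, k), dtype=np.int8)
        if scheme == "window_permute":
            # A uniform permutation read at a uniform offset is equivalent
            # to drawing k letters uniformly without replacement, in order.
            u = rng.random((chunk, int(lengths.max())))
            for i, wi in enumerate(widx):
                length = lengths[wi]
                pick = np.argpartition(u[i, :length], k)[:k]
                kmers[i] = encoded[wi][pick]
        else:  # kmer_shuffle
            for i, wi in enumerate(widx):
                start = rng.integers(0, lengths[wi] - k + 1)
                kmer = encoded[wi][start:start + k].copy()
                rng.shuffle(kmer)
                kmers[i] = kmer
        valid = np.all(kmers >= 0, axis=1)
        kmers = kmers[valid]
        if kmers.size:
            scores = pwm.scores[np.arange(k)[None, :], kmers].sum(axis=1)
            collected.append(scores[: remaining])
            remaining -= min(scores.size, remaining)
    out = np.sort(np.concatenate(collected))
    return NullScoreDistribution(scores=out, scheme=scheme, seed=seed)


@dataclass(frozen=True)
class SimilarityTrack:
    """Per-offset PWM score, empirical p and similarity index for one gene."""

    gene_id: str
    offsets: np.ndarray  # 5'-most-base offsets, ascending
    scores: np.ndarray  # bits; NaN where the k-mer was unscoreable
    pvalues: np.ndarray = field(repr=False)
    group: str | None = None

    @property
    def similarity_index(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return -np.log10(self.pvalues)

    def region_slice(self, region: tuple[int, int]) -> slice:
        lo = int(np.searchsorted(self.offsets, region[0], side="left"))
        hi = int(np.searchsorted(self.offsets, region[1], side="right"))
        return slice(lo, hi)

    def max_index_in(self, region: tuple[int, int] = PAUSE_REGION) -> float:
        vals = self.similarity_index[self.region_slice(region)]
        if vals.size == 0 or np.all(np.isnan(vals)):
            return np.nan
        return float(np.nanmax(vals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_id,
                "offset": self.offsets,
                "score_bits": self.scores,
                "p_value": self.pvalues,
                "similarity_index": self.similarity_index,
            }
        )


def scan_windows(
    windows: list[PromoterWindow],
    pwm: PositionWeightMatrix,
    null: NullScoreDistribution,
) -> list[SimilarityTrack]:
    """Score every k-mer of every window and attach empirical p-values."""
    if len(windows) == 0:
        raise ValueError("no windows to scan")
    tracks = []
    for window in windows:
        codes = window.codes
        if codes.size < pwm.k:
            logger.warning(
                "window %s shorter than k=%d; skipped", window.gene_id, pwm.k
            )
            continue
        scores = _window_kmer_scores(codes, pwm)
        offsets = window.start_offset + np.arange(scores.size)
        pvals = _empirical_pvalues(scores, null)
        tracks.append(
            SimilarityTrack(
                gene_id=window.gene_id, offsets=offsets,
                scores=scores, pvalues=pvals, group=window.group,
            )
        )
    return tracks


def best_match_per_gene(
    track: SimilarityTrack,
    window: PromoterWindow,
    region: tuple[int, int] = (0, 50),
) -> str | None:
    """The k-mer with the maximal raw score in ``region`` (5'-most on ties).

    Returns None (with a warning) when the region is entirely unscoreable;
    such genes are omitted from downstream logos.
    """
    sl = track.region_slice(region)
    scores = track.scores[sl]
    if scores.size == 0 or np.all(np.isnan(scores)):
        warnings.warn(f"gene {track.gene_id}: region {region} unscoreable")
        return None
    best = int(np.nanargmax(scores))  # nanargmax returns the first maximum
    offset = int(track.offsets[sl][best])
    k = len(window.sequence) - track.offsets.size + 1
    start = window.index_of(offset)
    return window.sequence[start:start + k].upper().replace("U", "T")


def average_profile(tracks: list[SimilarityTrack]) -> pd.DataFrame:
    """Per-offset mean similarity index over genes (NaN-aware) with counts."""
    if len(tracks) == 0:
        raise ValueError("no tracks")
    offsets = tracks[0].offsets
    matrix = np.stack([t.similarity_index for t in tracks])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(matrix, axis=0)
    count = np.sum(np.isfinite(matrix), axis=0)
    return pd.DataFrame(
        {"offset": offsets, "mean_similarity_index": mean, "n_genes": count}
    )


@dataclass(frozen=True)
class PauseComparisonResult:
    """KS and Welch-t comparison of per-gene pause-region similarity maxima."""

    values_a: np.ndarray
    values_b: np.ndarray
    label_a: str
    label_b: str
    region: tuple[int, int]
    ks_statistic: float
    ks_pvalue: float
    welch_t_statistic: float
    welch_t_pvalue: float

    @property
    def n_a(self) -> int:
        return self.values_a.size

    @property
    def n_b(self) -> int:
        return self.values_b.size

    def summary(self) -> str:
        lines = [
            f"Pause-region similarity comparison ({self.region[0]:+d}..{self.region[1]:+d})",
            f"  {self.label_a}: n={self.n_a}, mean max index={np.mean(self.values_a):.3f}",
            f"  {self.label_b}: n={self.n_b}, mean max index={np.mean(self.values_b):.3f}",
            f"  KS test:      D={self.ks_statistic:.4f}, p={self.ks_pvalue:.3g}",
            f"  Welch t-test: t={self.welch_t_statistic:.4f}, p={self.welch_t_pvalue:.3g}",
        ]
        return "\n".join(lines)


def compare_groups(
    tracks_by_group: dict[str, list[SimilarityTrack]],
    region: tuple[int, int] = PAUSE_REGION,
) -> PauseComparisonResult:
    """Two-sided two-sample KS + Welch t-test on per-gene region maxima."""
    if len(tracks_by_group) != 2:
        raise ValueError("exactly two groups are required")
    (label_a, tracks_a), (label_b, tracks_b) = tracks_by_group.items()
    values_a = np.array([t.max_index_in(region) for t in tracks_a])
    values_b = np.array([t.max_index_in(region) for t in tracks_b])
    values_a = values_a[np.isfinite(values_a)]
    values_b = values_b[np.isfinite(values_b)]
    if values_a.size < 2 or values_b.size < 2:
        raise ValueError("both groups need >= 2 genes with scoreable regions")
    ks = stats.ks_2samp(values_a, values_b, alternative="two-sided")
    tt = stats.ttest_ind(values_a, values_b, equal_var=False)
    return PauseComparisonResult(
        values_a=values_a, values_b=values_b,
        label_a=label_a, label_b=label_b, region=region,
        ks_statistic=float(ks.statistic), ks_pvalue=float(ks.pvalue),
        welch_t_statistic=float(tt.statistic), welch_t_pvalue=float(tt.pvalue),
    )


def heatmap_matrix(
    tracks: list[SimilarityTrack],
    order: str = "by_max_index",
    region: tuple[int, int] = PAUSE_REGION,
) -> pd.DataFrame:
    """Gene x offset similarity-index matrix (rows = genes).

    ``order="by_max_index"`` sorts rows by the maximum similarity index in
    ``region``, descending; ``order="input"`` keeps the input order.
    """
    if len(tracks) == 0:
        raise ValueError("no tracks")
    if order not in ("by_max_index", "input"):
        raise ValueError(f"unknown row order {order!r}")
    frame = pd.DataFrame(
        np.stack([t.similarity_index for t in tracks]),
        index=pd.Index([t.gene_id for t in tracks], name="gene_id"),
        columns=tracks[0].offsets,
    )
    if order == "by_max_index":
        strength = np.array([t.max_index_in(region) for t in tracks])
        frame = frame.iloc[np.argsort(-np.nan_to_num(strength, nan=-np.inf),
                                      kind="stable")]
    return frame


def positional_boxplot_stats(
    tracks: list[SimilarityTrack],
    centers: list[int] = (0, 10, 20, 30, 40),
    halfwidth: int = 5,
) -> dict:
    """Per-gene max similarity index in center+-halfwidth bins, plus
    Welch t p-values between adjacent centers."""
    per_center = {}
    for center in centers:
        region = (center - halfwidth, center + halfwidth)
        vals = np.array([t.max_index_in(region) for t in tracks])
        per_center[center] = vals[np.isfinite(vals)]
    adjacent = {}
    centers = list(centers)
    for c1, c2 in zip(centers, centers[1:]):
        a, b = per_center[c1], per_center[c2]
        if a.size > 1 and b.size > 1:
            if np.array_equal(a, b) or (np.ptp(a) == 0 and np.ptp(b) == 0
                                        and a[0] == b[0]):
                p = 1.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = np.nan
        adjacent[(c1, c2)] = p
    return {"values": per_center, "adjacent_welch_p": adjacent}


class PromoterScanModel:
    """Promoter-proximal motif-enrichment scan, statsmodels style.

    Parameters
    ----------
    windows : list of PromoterWindow
        TSS-anchored promoter sequences, optionally group-labelled.
    pwm : PositionWeightMatrix
        Consensus log-likelihood matrix (see :func:`nbescan.motif.build_pwm`).

    ``fit(null_n, seed)`` builds the permutation null and returns a
    :class:`PromoterScanResults` carrying tracks, profiles and group tests.
    """

    def __init__(self, windows: list[PromoterWindow], pwm: PositionWeightMatrix):
        if len(windows) == 0:
            raise ValueError("no windows supplied")
        self.windows = list(windows)
        self.pwm = pwm

    @classmethod
    def from_sequences(cls, sequences: dict[str, str], pwm: PositionWeightMatrix,
                       groups: dict[str, str] | None = None,
                       start_offset: int = WINDOW_START) -> "PromoterScanModel":
        groups = groups or {}
        windows = [
            PromoterWindow(gene_id=g, sequence=s, group=groups.get(g),
                           start_offset=start_offset)
            for g, s in sequences.items()
        ]
        return cls(windows, pwm)

    def fit(self, null_n: int = 100_000, seed: int = 0,
            scheme: str = "window_permute",
            region: tuple[int, int] = PAUSE_REGION) -> "PromoterScanResults":
        null = build_null(self.windows, self.pwm, n=null_n, seed=seed,
                          scheme=scheme)
        tracks = scan_windows(self.windows, self.pwm, null)
        return PromoterScanResults(model=self, null=null, tracks=tracks,
                                   region=region)


class PromoterScanResults:
    """Results of a promoter scan: tracks, profiles and group comparisons."""

    def __init__(self, model: PromoterScanModel, null: NullScoreDistribution,
                 tracks: list[SimilarityTrack], region: tuple[int, int]):
        self.model = model
        self.null = null
        self.tracks = tracks
        self.region = region
        self._windows_by_id = {w.gene_id: w for w in model.windows}

    def tracks_frame(self) -> pd.DataFrame:
        return pd.concat([t.to_frame() for t in self.tracks], ignore_index=True)

    def average_profile(self) -> pd.DataFrame:
        return average_profile(self.tracks)

    def heatmap(self, order: str = "by_max_index") -> pd.DataFrame:
        return heatmap_matrix(self.tracks, order=order, region=self.region)

    def best_match_logo_kmers(self, region: tuple[int, int] = (0, 50)) -> list[str]:
        kmers = []
        for track in self.tracks:
            kmer = best_match_per_gene(track, self._windows_by_id[track.gene_id],
                                       region=region)
            if kmer is not None:
                kmers.append(kmer)
        return kmers

    def compare_groups(self, region: tuple[int, int] | None = None
                       ) -> PauseComparisonResult:
        region = region or self.region
        by_group: dict[str, list[SimilarityTrack]] = {}
        for track in self.tracks:
            if track.group is not None:
                by_group.setdefault(track.group, []).append(track)
        return compare_groups(by_group, region=region)

    def plot_profile(self, ax=None):
        """Average similarity-index profile vs TSS offset (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        profile = self.average_profile()
        ax.plot(profile["offset"], profile["mean_similarity_index"])
        ax.set_xlabel("offset from TSS (bp)")
        ax.set_ylabel("mean similarity index (-log10 p)")
        return ax

    def plot_heatmap(self, ax=None, order: str = "by_max_index"):
        """Gene x offset similarity-index heat map (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        matrix = self.heatmap(order=order)
        im = ax.imshow(matrix.to_numpy(), aspect="auto",
                       extent=(matrix.columns[0], matrix.columns[-1],
                               matrix.shape[0], 0))
        ax.set_xlabel("offset from TSS (bp)")
        ax.set_ylabel("gene rank")
        plt.colorbar(im, ax=ax, label="similarity index (-log10 p)")
        return ax

    def summary(self) -> str:
        lines = [
            "Promoter scan results",
            f"  genes scanned : {len(self.tracks)}",
            f"  consensus     : {self.model.pwm.consensus.as_rna()}"
            f" (match p = {self.model.pwm.match_probability})",
            f"  null          : {self.null.n} scores, scheme={self.null.scheme},"
            f" seed={self.null.seed}",
        ]
        groups = {t.group for t in self.tracks if t.group is not None}
        if len(groups) == 2:
            lines.append(self.compare_groups().summary())
        return "\n".join(lines)
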