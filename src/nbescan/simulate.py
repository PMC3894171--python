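"""Seeded synthetic inputs for every pipeline stage.

Three generators, each a pure function of (config, seed):

- promoter windows with a degenerate NBE copy embedded near +25 at a
  group-specific probability (paused vs non-paused gene sets);
- RAPID-SELEX-style read pools where motif-bearing reads are enriched by
  a per-cycle factor without amplification;
- noisy Hill-shaped titration curves on a serial-dilution grid.

Every generator returns a ground-truth manifest so recovery tests can be
scored against what was actually planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .binding import TitrationSeries, hill_response, dilution_series
from .motif import ALPHABET, ConsensusMotif
from .scan import PromoterWindow, WINDOW_START, WINDOW_END
from .selex import ReadPool

__all__ = [
    "PromoterSimConfig",
    "SelexSimConfig",
    "BindingSimConfig",
    "simulate_promoters",
    "simulate_pools",
    "simulate_titration",
]

_UNIFORM = (0.25, 0.25, 0.25, 0.25)


def _random_sequences(rng: np.random.Generator, n: int, length: int,
                      background: np.ndarray) -> np.ndarray:
    """n x length array of base codes drawn i.i.d. from background."""
    return rng.choice(4, size=(n, length), p=background)


def _decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


@dataclass(frozen=True)
class PromoterSimConfig:
    """Synthetic TSS-anchored promoter set with planted NBE copies.

    Defaults mirror the promoter-proximal pausing setting: windows span
    -50..+150, motifs land at a truncated-normal offset centred on +25
    (s.d. 3), and paused genes carry a motif far more often (0.6) than
    non-paused genes (0.1).  At most one motif copy per window; each
    embedded position mutates independently at ``mutation_rate``.
    """

    n_paused: int = 500
    n_non_paused: int = 500
    embed_p_paused: float = 0.6
    embed_p_non_paused: float = 0.1
    motif: ConsensusMotif = field(default_factory=ConsensusMotif)
    mutation_rate: float = 0.10
    offset_mean: float = 25.0
    offset_sd: float = 3.0
    background: tuple[float, ...] = _UNIFORM
    window_start: int = WINDOW_START
    window_end: int = WINDOW_END
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.embed_p_paused, self.embed_p_non_paused,
                  self.mutation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.window_start <= self.offset_mean <= self.window_end:
            raise ValueError("offset distribution centre outside the window")


def simulate_promoters(config: PromoterSimConfig
                       ) -> tuple[list[PromoterWindow], list[dict]]:
    """Generate group-labelled windows and a truth manifest.

    The manifest lists, per embedded motif: gene_id, group, offset, the
    (possibly mutated) planted sequence and the mutated-position count.
    """
    rng = np.random.default_rng(config.seed)
    background = np.asarray(config.background, dtype=float)
    background = background / background.sum()
    length = config.window_end - config.window_start + 1
    k = config.motif.k
    motif_codes = config.motif.codes

    windows: list[PromoterWindow] = []
    manifest: list[dict] = []
    groups = [("paused", config.n_paused, config.embed_p_paused),
              ("non_paused", config.n_non_paused, config.embed_p_non_paused)]
    for group, n_genes, embed_p in groups:
        codes = _random_sequences(rng, n_genes, length, background)
        embed = rng.random(n_genes) < embed_p
        # truncated-normal embedding offsets, clipped so the motif fits
        lo, hi = config.window_start, config.window_end - k + 1
        for i in range(n_genes):
            gene_id = f"{group}_{i:05d}"
            if embed[i]:
                offset = np.nan
                while not (lo <= offset <= hi):
                    offset = round(rng.normal(config.offset_mean,
                                              config.offset_sd))
                offset = int(offset)
                planted = motif_codes.copy()
                mutated = rng.random(k) < config.mutation_rate
                for j in np.nonzero(mutated)[0]:
                    planted[j] = rng.choice(
                        [b for b in range(4) if b != motif_codes[j]]
                    )
                start = offset - config.window_start
                codes[i, start:start + k] = planted
                manifest.append({
                    "gene_id": gene_id, "group": group, "offset": offset,
                    "planted": _decode(planted),
                    "n_mutated": int(mutated.sum()),
                })
            windows.append(PromoterWindow(
                gene_id=gene_id, sequence=_decode(codes[i]), group=group,
                start_offset=config.window_start,
            ))
    return windows, manifest


@dataclass(frozen=True)
class SelexSimConfig:
    """RAPID-SELEX pool simulation: selection without amplification.

    A naive pool of ``pool_size`` reads contains a ``naive_fraction`` of
    motif-bearing reads (one exact motif copy at a random position over
    i.i.d. background).  Selection reweights motif-bearing reads by
    ``enrichment_factor ** cycles`` and resamples the same pool size; the
    control pool resamples the naive pool uniformly.
    """

    pool_size: int = 100_000
    read_length: int = 50
    naive_fraction: float = 0.01
    enrichment_factor: float = 5.0
    cycles: int = 2
    motif: ConsensusMotif = field(default_factory=ConsensusMotif)
    background: tuple[float, ...] = _UNIFORM
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.naive_fraction <= 1.0:
            raise ValueError("naive_fraction must lie in [0, 1]")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1")
        if self.read_length < self.motif.k:
            raise ValueError("reads must be at least as long as the motif")


def simulate_pools(config: SelexSimConfig
                   ) -> tuple[ReadPool, ReadPool, ReadPool, dict]:
    """Return (naive, selected, control) pools plus a truth manifest."""
    rng = np.random.default_rng(config.seed)
    background = np.asarray(config.background, dtype=float)
    background = background / background.sum()
    n = config.pool_size
    codes = _random_sequences(rng, n, config.read_length, background)
    bearing = rng.random(n) < config.naive_fraction
    k = config.motif.k
    starts = rng.integers(0, config.read_length - k + 1, size=n)
    for i in np.nonzero(bearing)[0]:
        codes[i, starts[i]:starts[i] + k] = config.motif.codes
    reads = ["".join(ALPHABET[c] for c in row) for row in codes]

    weights = np.where(bearing, config.enrichment_factor ** config.cycles, 1.0)
    weights = weights / weights.sum()
    selected_idx = rng.choice(n, size=n, replace=True, p=weights)
    control_idx = rng.choice(n, size=n, replace=True)

    naive = _pool_from_indices(reads, np.arange(n), "naive")
    selected = _pool_from_indices(reads, selected_idx, "selected")
    control = _pool_from_indices(reads, control_idx, "control")
    manifest = {
        "config": {**asdict(config), "motif": config.motif.as_rna()},
        "naive_bearing_fraction": float(bearing.mean()),
        "selected_bearing_fraction": float(bearing[selected_idx].mean()),
        "control_bearing_fraction": float(bearing[control_idx].mean()),
    }
    return naive, selected, control, manifest


def _pool_from_indices(reads: list[str], idx: np.ndarray, label: str
                       ) -> ReadPool:
    values, counts = np.unique(np.asarray(reads, dtype=object)[idx],
                               return_counts=True)
    return ReadPool(dict(zip(values.tolist(), counts.tolist())), label=label)


@dataclass(frozen=True)
class BindingSimConfig:
    """Noisy Hill titration: 12-point 2-fold dilution from 2 uM down.

    F-EMSA responses are fraction bound (baseline 0, amplitude 1, clipped
    to [0, 1]); FP responses use 80 mP baseline and 120 mP amplitude.
    """

    kd_nM: float = 44.0
    hill_n: float = 1.0
    assay: str = "femsa"
    noise_sd: float = 0.05
    top_nM: float = 2000.0
    points: int = 12
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd_nM <= 0:
            raise ValueError("Kd must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise s.d. must be >= 0")
        if self.assay not in ("femsa", "fp"):
            raise ValueError(f"unknown assay {self.assay!r}")


FP_BASELINE_MP = 80.0
FP_AMPLITUDE_MP = 120.0


def simulate_titration(config: BindingSimConfig
                       ) -> tuple[list[TitrationSeries], dict]:
    """Generate ``replicates`` noisy titration series plus the truth."""
    rng = np.random.default_rng(config.seed)
    conc = dilution_series(config.top_nM, config.points)
    if config.assay == "femsa":
        baseline, amplitude = 0.0, 1.0
    else:
        baseline, amplitude = FP_BASELINE_MP, FP_AMPLITUDE_MP
    clean = hill_response(conc, config.kd_nM, config.hill_n,
                          amplitude, baseline)
    series = []
    for _ in range(config.replicates):
        noisy = clean + rng.normal(0.0, config.noise_sd, size=conc.size)
        if config.assay == "femsa":
            noisy = np.clip(noisy, 0.0, 1.0)
        series.append(TitrationSeries(
            concentrations_nM=conc, responses=noisy, assay=config.assay,
            protein="sim", rna="sim",
        ))
    manifest = {"kd_nM": config.kd_nM, "hill_n": config.hill_n,
                "baseline": baseline, "amplitude": amplitude,
                "noise_sd": config.noise_sd, "seed": config.seed}
    return series, manifest
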