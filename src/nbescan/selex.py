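"""Motif enrichment in SELEX / nuclear run-on read pools.

Read pools are stored as unique sequences with multiplicities.  Motif
occurrences are counted with a fixed-length pattern and a Hamming-distance
mismatch budget (one mutation by default, mirroring PatScan-style
searches), normalized to multiplicity per million mapped reads (MPM), and
target-vs-control enrichment is assessed with a two-sided Fisher's exact
test on the motif-positive / motif-negative read counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .motif import ConsensusMotif, canonicalize, encode

__all__ = [
    "ReadPool",
    "MotifQuery",
    "EnrichmentResult",
    "find_matches",
    "dedupe_reads",
    "top_n_by_multiplicity",
    "count_pool_matches",
    "fisher_enrichment",
    "dominant_kmer",
    "variable_position_counts",
]


@dataclass(frozen=True)
class MotifQuery:
    """A fixed-length pattern matched with a Hamming mismatch budget."""

    pattern: ConsensusMotif
    max_mismatches: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.max_mismatches < self.pattern.k:
            raise ValueError(
                "max_mismatches must satisfy 0 <= m < pattern length"
            )


class ReadPool:
    """Unique sequences with multiplicities plus a total-read normalizer.

    ``total`` defaults to the sum of multiplicities; it may be larger when
    the pool is a subset of a bigger mapped-read set.
    """

    def __init__(self, counts: dict[str, int], total: int | None = None,
                 label: str = ""):
        self.counts = {canonicalize(s): int(m) for s, m in counts.items()}
        if any(m < 1 for m in self.counts.values()):
            raise ValueError("multiplicities must be >= 1")
        listed = sum(self.counts.values())
        self.total = listed if total is None else int(total)
        if self.total < listed:
            raise ValueError("total reads cannot be below listed multiplicities")
        self.label = label

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def __len__(self) -> int:
        return self.total

    def __eq__(self, other) -> bool:
        return (isinstance(other, ReadPool) and self.counts == other.counts
                and self.total == other.total)

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(items, columns=["sequence", "multiplicity"])


def dedupe_reads(reads: Iterable[str], label: str = "") -> ReadPool:
    """Collapse a read stream by exact identity, keeping multiplicities."""
    counter = Counter(canonicalize(r) for r in reads)
    return ReadPool(dict(counter), label=label)


def top_n_by_multiplicity(pool: ReadPool, n: int) -> list[str]:
    """The n highest-multiplicity unique sequences (lexicographic on ties)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(pool.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if n > len(ranked):
        import warnings
        warnings.warn(
            f"requested top {n} but pool has only {len(ranked)} unique reads"
        )
    return [seq for seq, _ in ranked[:n]]


def find_matches(sequence: str, query: MotifQuery) -> list[tuple[int, int]]:
    """All windows within the mismatch budget, as (1-based start, mismatches).

    Overlapping matches are all reported, ascending by start.  Ambiguous
    bases never match any pattern base.  A sequence shorter than the
    pattern yields no matches.
    """
    codes = encode(sequence)
    pat = query.pattern.codes
    k = pat.size
    if codes.size < k:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    mismatches = np.sum((windows != pat[None, :]) | (windows < 0), axis=1)
    hits = np.nonzero(mismatches <= query.max_mismatches)[0]
    return [(int(i) + 1, int(mismatches[i])) for i in hits]


def count_pool_matches(pool: ReadPool, query: MotifQuery) -> tuple[int, float]:
    """(motif-positive reads, MPM).  A read counts once however many
    windows match; positive reads are multiplicity-weighted; MPM is
    10^6 * positive / total."""
    if pool.total == 0:
        raise ValueError("MPM undefined for an empty pool")
    positive = sum(
        mult for seq, mult in pool.counts.items()
        if find_matches(seq, query)
    )
    return positive, 1e6 * positive / pool.total


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher's exact comparison of motif content in two read pools."""

    target_positive: int
    target_negative: int
    control_positive: int
    control_negative: int
    target_mpm: float
    control_mpm: float
    odds_ratio: float
    pvalue: float
    continuity_corrected: bool
    unit: str  # "reads" or "unique"

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [[self.target_positive, self.target_negative],
             [self.control_positive, self.control_negative]]
        )

    def summary(self) -> str:
        return (
            "Motif enrichment (Fisher's exact test, two-sided)\n"
            f"  unit: {self.unit}\n"
            f"  target : {self.target_positive} motif+ / "
            f"{self.target_negative} motif-  (MPM {self.target_mpm:.1f})\n"
            f"  control: {self.control_positive} motif+ / "
            f"{self.control_negative} motif-  (MPM {self.control_mpm:.1f})\n"
            f"  odds ratio = {self.odds_ratio:.3f}"
            f"{' (0.5 continuity correction)' if self.continuity_corrected else ''}\n"
            f"  p = {self.pvalue:.3g}"
        )


def _fisher_from_table(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Two-sided Fisher p and ad/bc odds ratio (Haldane 0.5 on zero cells)."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
        odds = (a2 * d2) / (b2 * c2)
    else:
        odds = (a * d) / (b * c)
    return odds, float(p), corrected


def fisher_enrichment(
    target: ReadPool,
    control: ReadPool,
    query: MotifQuery,
    unit: str = "reads",
) -> EnrichmentResult:
    """Fisher's exact test of motif-positive counts, target vs control.

    ``unit="reads"`` weights by multiplicity (default); ``unit="unique"``
    counts each unique sequence once.
    """
    if target.total == 0 or control.total == 0:
        raise ValueError("both pools must be non-empty")
    if unit not in ("reads", "unique"):
        raise ValueError(f"unknown counting unit {unit!r}")

    def counts(pool: ReadPool) -> tuple[int, int]:
        if unit == "reads":
            pos, _ = count_pool_matches(pool, query)
            return pos, pool.total - pos
        pos = sum(1 for seq in pool.counts if find_matches(seq, query))
        return pos, pool.n_unique - pos

    tp, tn = counts(target)
    cp, cn = counts(control)
    odds, p, corrected = _fisher_from_table(tp, tn, cp, cn)
    return EnrichmentResult(
        target_positive=tp, target_negative=tn,
        control_positive=cp, control_negative=cn,
        target_mpm=1e6 * tp / (tp + tn), control_mpm=1e6 * cp / (cp + cn),
        odds_ratio=odds, pvalue=p, continuity_corrected=corrected, unit=unit,
    )


def dominant_kmer(pool: ReadPool, k: int, top_n: int = 3000
                  ) -> tuple[str, float]:
    """Most widespread k-mer among the top_n highest-multiplicity reads.

    Presence, not occurrence count: a k-mer scores one per sequence that
    contains it.  Ties resolve to the lexicographically smallest k-mer.
    Returns (k-mer, fraction of the top_n sequences containing it).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    top = top_n_by_multiplicity(pool, min(top_n, pool.n_unique))
    presence: Counter[str] = Counter()
    any_long_enough = False
    for seq in top:
        if len(seq) < k:
            continue
        any_long_enough = True
        presence.update({seq[i:i + k] for i in range(len(seq) - k + 1)})
    if not any_long_enough:
        raise ValueError(f"k={k} exceeds every sequence length in the pool")
    best = min(presence.items(), key=lambda kv: (-kv[1], kv[0]))
    return best[0], best[1] / len(top)


def variable_position_counts(pool: ReadPool, query: MotifQuery) -> pd.DataFrame:
    """Per-position single-mismatch motif counts (one row per pattern
    position allowed to vary), plus the exact-match row.

    A read is assigned to position i when its best match to the pattern
    has exactly one mismatch located at i; exact-match reads are reported
    in a separate row with position 0.
    """
    k = query.pattern.k
    rows = {"exact": 0}
    rows.update({i: 0 for i in range(1, k + 1)})
    for seq, mult in pool.counts.items():
        hits = find_matches(seq, MotifQuery(query.pattern, max_mismatches=1))
        if not hits:
            continue
        if any(m == 0 for _, m in hits):
            rows["exact"] += mult
            continue
        # locate the mismatch position of the first (5'-most) 1-mismatch hit
        start, _ = hits[0]
        window = encode(seq)[start - 1:start - 1 + k]
        mm_pos = int(np.nonzero(window != query.pattern.codes)[0][0]) + 1
        rows[mm_pos] += mult
    records = [("exact", rows["exact"], 1e6 * rows["exact"] / pool.total)]
    records += [
        (str(i), rows[i], 1e6 * rows[i] / pool.total) for i in range(1, k + 1)
    ]
    return pd.DataFrame(records, columns=["variable_position", "reads", "mpm"])
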