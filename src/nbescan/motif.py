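"""Consensus-derived position weight matrices and sequence logos.

The NELF-E binding element (NBE, consensus ``CUGAGGA``) is modelled as a
log-likelihood position weight matrix (PWM): at each position the consensus
base carries probability ``match_probability`` and the remaining mass is
split equally among the other three bases.  Scores are log2 ratios against
a background base distribution, so they are in bits and the consensus
k-mer is the unique global maximum over all k-mers.

RNA (U) and DNA (T) alphabets are canonicalized to a single internal DNA
alphabet ``ACGT``; inputs may freely mix the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

__all__ = [
    "ALPHABET",
    "ConsensusMotif",
    "PositionWeightMatrix",
    "SequenceLogo",
    "canonicalize",
    "encode",
    "build_pwm",
    "score_kmer",
    "logo_from_kmers",
]


def canonicalize(sequence: str) -> str:
    """Uppercase and map U->T so RNA and DNA inputs compare directly."""
    return sequence.upper().replace("U", "T")


def encode(sequence: str) -> np.ndarray:
    """Encode a canonical sequence as int codes A=0,C=1,G=2,T=3; other -> -1."""
    seq = canonicalize(sequence)
    codes = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return codes


@dataclass(frozen=True)
class ConsensusMotif:
    """An unambiguous nucleotide consensus (default the NBE, CUGAGGA)."""

    sequence: str = "CUGAGGA"

    def __post_init__(self) -> None:
        canonical = canonicalize(self.sequence)
        if len(canonical) < 1:
            raise ValueError("consensus must have length >= 1")
        invalid = set(canonical) - set(ALPHABET)
        if invalid:
            raise ValueError(
                f"consensus contains non-ACGT/U symbols: {sorted(invalid)}"
            )
        object.__setattr__(self, "sequence", canonical)

    @property
    def k(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)

    def as_rna(self) -> str:
        return self.sequence.replace("T", "U")


@dataclass(frozen=True)
class PositionWeightMatrix:
    """k x 4 log2-likelihood-ratio scores (bits) with their background.

    ``scores[i, b] = log2(p(b | i) / background[b])`` where the consensus
    base at position i has probability ``match_probability``.
    """

    scores: np.ndarray
    background: np.ndarray
    consensus: ConsensusMotif
    match_probability: float

    @property
    def k(self) -> int:
        return self.scores.shape[0]

    def probabilities(self) -> np.ndarray:
        """Implied per-position base probabilities (rows sum to 1)."""
        return np.exp2(self.scores) * self.background[None, :]

    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.scores.min(axis=1).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, columns=list(ALPHABET),
            index=pd.RangeIndex(self.k, name="position"),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, consensus: ConsensusMotif | None = None,
                 background: np.ndarray | None = None,
                 match_probability: float = float("nan")) -> "PositionWeightMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        scores = frame[list(ALPHABET)].to_numpy(dtype=float)
        if background is None:
            background = np.full(4, 0.25)
        if consensus is None:
            consensus = ConsensusMotif(
                "".join(ALPHABET[i] for i in scores.argmax(axis=1))
            )
        return cls(scores=scores, background=np.asarray(background, float),
                   consensus=consensus, match_probability=match_probability)


def build_pwm(
    consensus: ConsensusMotif | str,
    match_probability: float = 0.85,
    background: np.ndarray | None = None,
) -> PositionWeightMatrix:
    """Build the log-likelihood PWM from a consensus.

    Parameters
    ----------
    consensus : ConsensusMotif or str
        Unambiguous consensus; U and T interchangeable.
    match_probability : float
        Probability mass on the consensus base per position, in (0.25, 1).
        The remaining mass is split equally among the other three bases.
    background : array-like of 4 floats, optional
        Background base probabilities (A, C, G, T); default uniform.
    """
    if isinstance(consensus, str):
        consensus = ConsensusMotif(consensus)
    if not np.isfinite(match_probability) or not 0.25 < match_probability < 1.0:
        raise ValueError(
            f"match_probability must be in (0.25, 1), got {match_probability!r}"
        )
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or np.any(background <= 0):
        raise ValueError("background must be 4 strictly positive probabilities")
    if not np.isclose(background.sum(), 1.0, atol=1e-9):
        raise ValueError("background must sum to 1")

    off_probability = (1.0 - match_probability) / 3.0
    probs = np.full((consensus.k, 4), off_probability)
    probs[np.arange(consensus.k), consensus.codes] = match_probability
    scores = np.log2(probs / background[None, :])
    return PositionWeightMatrix(
        scores=scores, background=background,
        consensus=consensus, match_probability=float(match_probability),
    )


def score_kmer(pwm: PositionWeightMatrix, kmer: str) -> float:
    """Sum of per-position PWM scores of an unambiguous k-mer, in bits.

    Raises ``ValueError`` on a length mismatch or ambiguous base; callers
    scanning windows treat that as an unscoreable window.
    """
    codes = encode(kmer)
    if codes.size != pwm.k:
        raise ValueError(f"k-mer length {codes.size} != PWM length {pwm.k}")
    if np.any(codes < 0):
        raise ValueError(f"k-mer {kmer!r} contains an ambiguous base")
    return float(pwm.scores[np.arange(pwm.k), codes].sum())


@dataclass(frozen=True)
class SequenceLogo:
    """Per-position base frequencies and information content of a k-mer set."""

    frequencies: np.ndarray  # L x 4, rows sum to 1
    information_bits: np.ndarray = field(repr=False)  # length L, in [0, 2]
    n: int = 0

    @property
    def length(self) -> int:
        return self.frequencies.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.frequencies, columns=list(ALPHABET),
            index=pd.RangeIndex(self.length, name="position"),
        )
        frame["IC_bits"] = self.information_bits
        return frame

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f")


def logo_from_kmers(kmers: list[str]) -> SequenceLogo:
    """Base-frequency logo of equal-length k-mers.

    Information content is ``2 - H`` bits per position (Shannon entropy in
    bits); no small-sample correction is applied, so the logo is a pure
    function of the observed frequencies.
    """
    if len(kmers) == 0:
        raise ValueError("need at least one k-mer to build a logo")
    codes = np.stack([encode(k) for k in kmers])
    if codes.ndim != 2:
        raise ValueError("all k-mers must have equal length")
    if np.any(codes < 0):
        raise ValueError("k-mers must be unambiguous ACGT/U")
    n, length = codes.shape
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)], axis=1)
    freqs = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    info = np.clip(2.0 - entropy, 0.0, 2.0)
    return SequenceLogo(frequencies=freqs, information_bits=info, n=n)
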