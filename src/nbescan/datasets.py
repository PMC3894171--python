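"""Published NELF-E binding-affinity measurements used as worked inputs.

Replicate-averaged dissociation constants (mean +- s.d., nM) of NELF-E
constructs for the SELEX aptamer NApt1min, HIV-1 TAR and related RNAs, by
fluorescence EMSA and fluorescence polarization.  Censored entries are
lower bounds (e.g. Kd > 2000 nM); 'ND' measurements are omitted.  These
rows feed the ddG specificity comparisons and the fold-change arithmetic.
"""

from __future__ import annotations

import pandas as pd

from .binding import AffinityEstimate

__all__ = ["reference_affinities", "reference_sequences", "get_affinity"]

# protein, rna, assay, n, kd_nM, sd_nM, censored
_AFFINITY_ROWS = [
    ("dNELF-E", "NApt1min", "femsa", 3, 44.0, 22.0, False),
    ("dNELF-E", "NApt1min", "fp", 3, 21.0, 7.0, False),
    ("dNELF-E", "NApt25min", "femsa", 3, 53.0, 9.0, False),
    ("dNELF-E", "NApt25min", "fp", 3, 30.0, 2.0, False),
    ("dNELF-E", "NApt1+hairpin", "femsa", 3, 810.0, 50.0, False),
    ("dNELF-E", "NApt1+hairpin", "fp", 3, 470.0, 170.0, False),
    ("dNELF-E", "NApt1(3G:Amut)", "femsa", 1, 2000.0, 0.0, True),
    ("dNELF-E", "NApt1-Dstem", "femsa", 3, 205.0, 20.0, False),
    ("dNELF-E", "NApt1-Dstem", "fp", 3, 270.0, 130.0, False),
    ("dNELF-E", "NApt1NBEmut", "femsa", 2, 880.0, 170.0, False),
    ("dNELF-E", "TAR", "femsa", 3, 350.0, 35.0, False),
    ("dNELF-E", "TAR", "fp", 3, 130.0, 0.0, True),
    ("dNELF-E", "TAR+A", "femsa", 3, 59.0, 2.0, False),
    ("dNELF-E", "TAR+A", "fp", 3, 82.0, 1.0, False),
    ("dNELF-E", "TAR-DhNBE", "femsa", 3, 2000.0, 0.0, True),
    ("hNELF-E", "NApt1min", "femsa", 3, 420.0, 90.0, False),
    ("hNELF-E", "NApt1min", "fp", 3, 140.0, 10.0, False),
    ("hNELF-E", "TAR", "femsa", 3, 300.0, 20.0, False),
    ("hNELF-E", "TAR", "fp", 3, 200.0, 10.0, False),
    ("hNELF-E", "TAR+A", "femsa", 3, 250.0, 20.0, False),
    ("hNELF-E", "TAR+A", "fp", 3, 250.0, 20.0, False),
    ("hNELF-E", "TAR-DhNBE", "femsa", 3, 2000.0, 0.0, True),
    ("dNELF-E(mut)", "NApt1min", "femsa", 2, 350.0, 50.0, False),
    ("dNELF-E(mut)", "NApt1min", "fp", 2, 95.0, 6.0, False),
    ("dNELF-E(mut)", "TAR", "femsa", 2, 270.0, 10.0, False),
    ("dNELF-E(mut)", "TAR", "fp", 2, 130.0, 10.0, False),
    ("dNELF-E(mut)", "TAR+A", "femsa", 2, 280.0, 30.0, False),
    ("dNELF-E(mut)", "TAR+A", "fp", 2, 120.0, 10.0, False),
    ("hNELF-E(mut)", "TAR", "femsa", 3, 258.0, 17.0, False),
    ("hNELF-E(mut)", "TAR", "fp", 3, 153.0, 7.0, False),
    ("hNELF-E(mut)", "TAR+A", "femsa", 3, 233.0, 40.0, False),
    ("hNELF-E(mut)", "TAR+A", "fp", 3, 170.0, 5.0, False),
]

# RNA sequences tested (5'->3'); the NBE consensus is CUGAGGA.  TAR+A is
# wild-type HIV-1 TAR with a single adenosine inserted in the loop,
# creating a perfect NBE.
_RNA_SEQUENCES = {
    "NApt1min": "GGCCCCACUGAGGAUGCCCACGGGCGAUUGGGGCCA",
    "NApt25min": "GGUCUCCAACUGAGGAUACCGCUCGAGGAAGCGAGUGGCGAUUUGGAGACCU",
    "NApt1+hairpin": "GGCCCCACUGAGGAUGCCCACGGGCGUCCUCAGUGGGGCCA",
    "NApt1(3G:Amut)": "GGCCCCACUAAAAAUGCCCACGGGCGAUUGGGGCCA",
    "NApt1-Dstem": "GGGGACUGAGGAGCAACACGGGCGAUUGGGGCCA",
    "NApt1NBEmut": "GGCCCCAUCAAAGAUGCCCACGGGCGAUUGGGGCCA",
    "TAR": "GGUCUCUCUGGUUAGACCAGAUCUGAGCCUGGGAGCUCUCUGGCUAACUAGGGAACC",
    "TAR+A": "GGUCUCUCUGGUUAGACCAGAUCUGAGCCUGAGGAGCUCUCUGGCUAACUAGGGAACC",
}


def reference_affinities() -> pd.DataFrame:
    """All published replicate-averaged Kd rows as a tidy DataFrame."""
    return pd.DataFrame(
        _AFFINITY_ROWS,
        columns=["protein", "rna", "assay", "n", "kd_nM", "sd_nM", "censored"],
    )


def reference_sequences() -> dict[str, str]:
    """RNA sequences (5'->3', RNA alphabet) keyed by the names used in
    :func:`reference_affinities`."""
    return dict(_RNA_SEQUENCES)


def get_affinity(protein: str, rna: str, assay: str = "femsa"
                 ) -> AffinityEstimate:
    """One published Kd row as an :class:`AffinityEstimate`."""
    for p, r, a, n, kd, sd, censored in _AFFINITY_ROWS:
        if (p, r, a) == (protein, rna, assay):
            if censored:
                return AffinityEstimate(
                    kd_nM=kd, sd_nM=0.0, n=n, assay=a, protein=p, rna=r,
                    censored=True, bound_nM=kd,
                )
            return AffinityEstimate(kd_nM=kd, sd_nM=sd, n=n, assay=a,
                                    protein=p, rna=r)
    raise KeyError(f"no published measurement for ({protein}, {rna}, {assay})")
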