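"""Synthetic reference sequences and primer definitions.

The coordinate system of the whole package is the MasD protein of the
alkane-degrading strain HxN1: the diagnostic motif sits at position 435 and
the catalytically active cysteine at position 477 (1-based anchor
coordinates), and OTU distances are computed over anchor columns 398-500.
The genuine HxN1 protein is a database sequence; this module instead builds
a *synthetic* anchor — a deterministic random protein carrying the motif and
the catalytic cysteine at exactly those coordinates — so that every
coordinate-dependent operation can be exercised without external downloads.
Synthetic stand-ins for the off-target families (NmsA, BssA, Pfl) are
generated the same way, scrubbed of the six MasD motifs.

All sequences here are generated, not biological; analyses of real data
should load a real panel via :class:`massdiv.orfscreen.ReferencePanel`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MOTIFS",
    "AMINO_ACIDS",
    "FORWARD_PRIMER",
    "REVERSE_PRIMER",
    "FORWARD_PRIMER_REALIZED",
    "REVERSE_PRIMER_REALIZED",
    "MOTIF_POSITION_1BASED",
    "CATALYTIC_POSITION_1BASED",
    "REGION_1BASED",
    "ANCHOR_PROTEIN",
    "ANCHOR_FRAGMENT",
    "FRAGMENT_START",
    "ANCHOR_16S",
    "OFFTARGET_PROTEINS",
    "iupac_expand",
]

#: The six diagnostic MasD motifs screened for after translation.
MOTIFS = ("FECIR", "FECIK", "FECQR", "FECVR", "FDCIR", "FDNIA")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Degenerate amplification primers (5'->3'); the reverse primer anneals on
#: the opposite strand, so reads carry its reverse complement near their 3' end.
FORWARD_PRIMER = "TCGGACGCGTGCAACGMYCTGA"
REVERSE_PRIMER = "TCGTCRTTGCCCCAYTTNGG"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_expand(code: str) -> str:
    """Bases matched by a single IUPAC nucleotide code."""
    return _IUPAC.get(code.upper(), "")


def _realize(primer: str) -> str:
    # first listed base of each degeneracy; deterministic
    return "".join(iupac_expand(c)[0] for c in primer)


#: Concrete (non-degenerate) primer realizations used by the simulator.
FORWARD_PRIMER_REALIZED = _realize(FORWARD_PRIMER)
REVERSE_PRIMER_REALIZED = _realize(REVERSE_PRIMER)

MOTIF_POSITION_1BASED = 435
CATALYTIC_POSITION_1BASED = 477
#: Anchor columns of the OTU clustering region (1-based, inclusive).
REGION_1BASED = (398, 500)

_ANCHOR_LENGTH = 550
#: 0-based start of the simulated amplicon fragment within the anchor
#: (anchor position 395, where the forward primer anneals).
FRAGMENT_START = 394
_FRAGMENT_END = 520


def _scrub_motifs(seq: list[str], rng: np.random.Generator, protected: set[int]) -> None:
    """Destroy accidental motif occurrences outside protected columns."""
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        for motif in MOTIFS:
            start = s.find(motif)
            while start != -1:
                cols = set(range(start, start + len(motif)))
                if not cols <= protected:
                    pos = next(iter(sorted(cols - protected)))
                    choices = [a for a in AMINO_ACIDS if a != seq[pos]]
                    seq[pos] = choices[rng.integers(len(choices))]
                    changed = True
                    break
                start = s.find(motif, start + 1)
            if changed:
                break


def _random_protein(length: int, rng: np.random.Generator) -> list[str]:
    return [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length)]


def _build_anchor() -> str:
    rng = np.random.default_rng(20150327)
    seq = _random_protein(_ANCHOR_LENGTH, rng)
    m0 = MOTIF_POSITION_1BASED - 1
    seq[m0 : m0 + 5] = list(MOTIFS[0])
    seq[CATALYTIC_POSITION_1BASED - 1] = "C"
    protected = set(range(m0, m0 + 5))
    _scrub_motifs(seq, rng, protected)
    # the scrub must not have touched the designed features
    s = "".join(seq)
    assert s[m0 : m0 + 5] == MOTIFS[0]
    assert s[CATALYTIC_POSITION_1BASED - 1] == "C"
    return s


def _build_offtarget(seed: int, length: int = 500) -> str:
    rng = np.random.default_rng(seed)
    seq = _random_protein(length, rng)
    _scrub_motifs(seq, rng, set())
    return "".join(seq)


def _build_16s(length: int = 1400) -> str:
    rng = np.random.default_rng(16)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


#: Synthetic MasD anchor protein (motif at 435, catalytic Cys at 477, 1-based).
ANCHOR_PROTEIN = _build_anchor()

#: The amplicon-covered part of the anchor (positions 395-520), the ancestor
#: from which simulated OTU reference proteins are evolved.
ANCHOR_FRAGMENT = ANCHOR_PROTEIN[FRAGMENT_START:_FRAGMENT_END]

#: Synthetic members of the off-target glycyl-radical-enzyme families that
#: the degenerate primers co-amplify.
OFFTARGET_PROTEINS = {
    "NmsA": _build_offtarget(6521),
    "BssA": _build_offtarget(6522),
    "Pfl": _build_offtarget(6523),
}

#: Synthetic 16S rRNA gene stand-in used by the strain-pair simulator.
ANCHOR_16S = _build_16s()
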