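"""Shared global-alignment machinery.

Every identity computation in the package (threshold calibration, region
extraction, family classification, OTU distances) goes through the same
aligner and the same identity convention so that numbers are comparable
across modules:

* global alignment with affine gap penalties, terminal gaps free;
* percent identity = identical columns / aligned columns, where terminal
  gap columns are excluded from the denominator and internal gap columns
  count as mismatches.

The terminal-gap exclusion makes identity robust to comparing a partial
amplicon-derived fragment against a full-length reference.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["get_aligner", "percent_identity", "align_to_anchor_columns"]


@lru_cache(maxsize=8)
def get_aligner(alphabet: str = "protein",
                end_gaps_free: bool = True) -> Align.PairwiseAligner:
    """Return a module-wide aligner for ``alphabet`` ('protein' or 'nucleotide').

    Protein scoring is BLOSUM62 with gap open -11 / extend -1; nucleotide
    scoring is match +2 / mismatch -3 with gap open -5 / extend -2.
    With ``end_gaps_free`` (default) terminal gaps cost nothing — the right
    mode for fragment-vs-reference comparisons; without it the alignment is
    forced end to end.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    elif alphabet == "nucleotide":
        aligner.match_score = 2.0
        aligner.mismatch_score = -3.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    if end_gaps_free:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def _sanitize(seq: str, alphabet: str) -> str:
    """Replace residues missing from the scoring matrix by a scored wildcard.

    BLOSUM62 lacks a handful of IUPAC ambiguity codes; they are mapped to
    'X' (protein) / 'N' (nucleotide) so alignment never crashes on
    degenerate input. '*' (stop) is kept for protein — BLOSUM62 scores it.
    """
    seq = seq.upper()
    if alphabet == "protein":
        allowed = set("ARNDCQEGHILKMFPSTWYVBZX*")
        return "".join(c if c in allowed else "X" for c in seq)
    allowed = set("ACGTN")
    return "".join(c if c in allowed else "N" for c in seq)


def _alignment_identity(alignment) -> tuple[int, int]:
    """(identical, aligned) column counts; terminal gap columns excluded."""
    indices = alignment.indices  # (2, n_columns); -1 marks a gap
    a_idx, b_idx = indices[0], indices[1]
    both = (a_idx >= 0) & (b_idx >= 0)
    if not both.any():
        return 0, 0
    cols = np.where(both)[0]
    start, stop = cols[0], cols[-1] + 1  # trim terminal overhangs
    a = np.frombuffer(str(alignment[0]).encode(), dtype="S1")
    b = np.frombuffer(str(alignment[1]).encode(), dtype="S1")
    window = slice(start, stop)
    ident = int(((a[window] == b[window]) & both[window]).sum())
    return ident, stop - start


def percent_identity(
    a: str, b: str, alphabet: str = "protein", terminal_gaps: str = "exclude"
) -> float:
    """Percent identity of the best global alignment of ``a`` and ``b``.

    With ``terminal_gaps="exclude"`` (default) the denominator is the
    aligned span only — appropriate when comparing a partial fragment to a
    full-length reference.  ``terminal_gaps="count"`` divides by all
    alignment columns instead, penalizing unaligned overhangs — the right
    semantics when two sequences are expected to correspond end to end.
    ``terminal_gaps="shorter"`` divides by the shorter sequence length,
    a coverage-aware identity for fragment-vs-database comparisons where a
    small well-matching window must not masquerade as overall similarity.
    Symmetric in ``a`` and ``b``; returns a value in [0, 100].
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if terminal_gaps not in ("exclude", "count", "shorter"):
        raise ValueError(f"unknown terminal_gaps mode {terminal_gaps!r}")
    if b < a:  # canonical argument order: aligner tie-breaks would
        a, b = b, a  # otherwise make identity asymmetric on ties
    # end-to-end identity uses a strict global alignment, otherwise free
    # terminal gaps would shunt divergent regions into unpenalized overhangs
    aligner = get_aligner(alphabet, end_gaps_free=(terminal_gaps != "count"))
    alignment = aligner.align(_sanitize(a, alphabet), _sanitize(b, alphabet))[0]
    ident, ncols = _alignment_identity(alignment)
    if terminal_gaps == "count":
        ncols = alignment.length
    elif terminal_gaps == "shorter":
        ncols = min(len(a), len(b))
    if ncols == 0:
        return 0.0
    return 100.0 * ident / ncols


def align_to_anchor_columns(anchor: str, query: str, alphabet: str = "protein"):
    """Align ``query`` to ``anchor`` and return per-anchor-column query indices.

    Returns ``(col_map, identity_pct)`` where ``col_map[i]`` is the 0-based
    query index aligned to anchor column ``i``, or -1 for a gap.  This is the
    primitive behind catalytic-residue checks and region extraction.
    """
    aligner = get_aligner(alphabet)
    alignment = aligner.align(_sanitize(anchor, alphabet), _sanitize(query, alphabet))[0]
    indices = alignment.indices
    a_idx, q_idx = indices[0], indices[1]
    col_map = np.full(len(anchor), -1, dtype=int)
    mask = a_idx >= 0
    col_map[a_idx[mask]] = q_idx[mask]
    ident, ncols = _alignment_identity(alignment)
    identity = 100.0 * ident / ncols if ncols else 0.0
    return col_map, identity
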