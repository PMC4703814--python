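"""Read-level quality control and a simplified de novo chimera screen.

Filters follow the strict amplicon-QC recipe for homopolymer-prone
pyrosequencing data: reads are removed if they mismatch the forward primer,
are shorter than 200 bp after trimming, contain a homopolymer run longer
than 8 bp, have a mean Phred quality below 20, or contain any ambiguity
codes.  Rules are applied in a fixed order and every read is accounted for
in a per-rule ledger under its first failing rule.

The chimera screen is a deliberately simple abundance-ordered two-parent
scorer (a pluggable stand-in with the same contract as full-featured
chimera detectors, not a reimplementation of any of them): candidate
parents must already have been accepted and be at least twice as abundant
as the query; the query is split at a small grid of crossover points and
flagged when its best two-parent segmental identity clearly exceeds its
best single-parent identity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import anchors
from ._align import percent_identity

__all__ = [
    "AmpliconRead",
    "QCParams",
    "QCReport",
    "match_primer",
    "max_homopolymer_run",
    "filter_reads",
    "demultiplex",
    "detect_chimeras",
]

VERDICTS = ("pass", "fail_primer", "fail_length", "fail_homopolymer",
            "fail_quality", "fail_ambiguity", "fail_chimera")


@dataclass
class AmpliconRead:
    """A barcoded nucleotide read with per-base Phred qualities."""

    id: str
    nucleotides: str
    qualities: list[int] | None = None
    barcode: str | None = None
    site: str | None = None

    def __post_init__(self) -> None:
        if not self.nucleotides:
            raise ValueError("read has empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.nucleotides):
            raise ValueError("qualities and nucleotides differ in length")


@dataclass
class QCParams:
    """Thresholds of the quality filters (defaults per the strict recipe)."""

    max_primer_mismatch: int = 0
    min_length: int = 200
    max_homopolymer: int = 8
    min_avg_quality: float = 20.0
    allow_ambiguities: bool = False
    chimera_score_threshold: float = 0.05
    trim_reverse_primer: bool = True
    run_chimera_check: bool = True

    def __post_init__(self) -> None:
        if min(self.max_primer_mismatch, self.min_length, self.max_homopolymer,
               self.min_avg_quality, self.chimera_score_threshold) < 0:
            raise ValueError("QC thresholds must be >= 0")


@dataclass
class QCReport:
    """Per-read verdicts plus per-rule counts; counts sum to the input size."""

    counts: Counter = field(default_factory=Counter)
    verdicts: dict[str, str] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def record(self, read_id: str, verdict: str, note: str | None = None) -> None:
        self.counts[verdict] += 1
        self.verdicts[read_id] = verdict
        if note:
            self.notes[read_id] = note


def _iupac_match(pattern_base: str, read_base: str) -> bool:
    """Does primer code ``pattern_base`` cover read base ``read_base``?

    Read-side ambiguity counts as a mismatch unless every base it could be
    is covered by the primer's degeneracy.
    """
    allowed = set(anchors.iupac_expand(pattern_base))
    observed = set(anchors.iupac_expand(read_base)) or {read_base}
    return observed <= allowed


def match_primer(
    read: AmpliconRead | str,
    primers: Sequence[str],
    max_mismatch: int = 0,
) -> tuple[bool, int | None, int]:
    """Match the read 5' end against a list of IUPAC primers.

    Returns ``(matched, primer_index, mismatches)`` for the best primer
    (fewest mismatches, ties to the lowest index).  A read shorter than a
    primer scores that primer's full length in mismatches.
    """
    if not primers:
        raise ValueError("primer list is empty")
    seq = read.nucleotides if isinstance(read, AmpliconRead) else read
    seq = seq.upper()
    best = (len(primers[0]) + 1, 0)
    for idx, primer in enumerate(primers):
        if len(seq) < len(primer):
            mm = len(primer)
        else:
            mm = sum(not _iupac_match(p, s) for p, s in zip(primer, seq))
        if mm < best[0]:
            best = (mm, idx)
    mm, idx = best
    if mm <= max_mismatch:
        return True, idx, mm
    return False, None, mm


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of a single repeated base."""
    if not seq:
        raise ValueError("empty sequence")
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def _find_reverse_primer_tail(seq: str, reverse_primer: str,
                              max_mismatch: int = 2) -> int | None:
    """Start of the reverse-complemented reverse primer near the 3' end."""
    pattern = _revcomp_iupac(reverse_primer)
    plen = len(pattern)
    lo = max(0, len(seq) - plen - 10)
    best = None
    for start in range(lo, len(seq) - plen + 1):
        mm = sum(not _iupac_match(p, s)
                 for p, s in zip(pattern, seq[start:start + plen]))
        if mm <= max_mismatch and (best is None or mm < best[1]):
            best = (start, mm)
    return best[0] if best else None


def _revcomp_iupac(nt: str) -> str:
    comp = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
    return nt.translate(comp)[::-1]


def demultiplex(reads: Iterable[AmpliconRead],
                barcode_map: dict[str, str]) -> list[AmpliconRead]:
    """Assign sites by exact barcode prefix and strip the barcode.

    ``barcode_map`` maps barcode -> site.  Reads with no matching barcode
    are kept with ``site=None`` (they will fail the primer rule downstream,
    since the unstripped barcode precedes the primer).
    """
    lengths = sorted({len(b) for b in barcode_map}, reverse=True)
    out = []
    for read in reads:
        hit = None
        for ln in lengths:
            prefix = read.nucleotides[:ln]
            if prefix in barcode_map:
                hit = (prefix, barcode_map[prefix])
                break
        if hit:
            out.append(AmpliconRead(
                id=read.id,
                nucleotides=read.nucleotides[len(hit[0]):],
                qualities=None if read.qualities is None
                          else read.qualities[len(hit[0]):],
                barcode=hit[0], site=hit[1],
            ))
        else:
            out.append(read)
    return out


def filter_reads(
    reads: Iterable[AmpliconRead],
    params: QCParams | None = None,
    primers: Sequence[str] = (anchors.FORWARD_PRIMER,),
    reverse_primer: str | None = anchors.REVERSE_PRIMER,
) -> tuple[list[AmpliconRead], QCReport]:
    """Apply the read-level filters in fixed order; trim primers off survivors.

    Order: primer -> length -> homopolymer -> quality -> ambiguity ->
    chimera.  A read failing several rules is counted once under the first.
    Kept reads are returned with the forward primer (and, when found, the
    reverse-primer tail) trimmed.  Reads must already be demultiplexed
    (barcode stripped) — see :func:`demultiplex`.
    """
    if params is None:
        params = QCParams()
    report = QCReport()
    kept: list[AmpliconRead] = []
    for read in reads:
        matched, _idx, mm = match_primer(read, primers, params.max_primer_mismatch)
        if not matched:
            report.record(read.id, "fail_primer")
            continue
        plen = len(primers[_idx])
        seq = read.nucleotides[plen:]
        quals = None if read.qualities is None else read.qualities[plen:]
        if params.trim_reverse_primer and reverse_primer:
            tail = _find_reverse_primer_tail(seq, reverse_primer)
            if tail is not None:
                seq = seq[:tail]
                quals = None if quals is None else quals[:tail]
        if len(seq) < params.min_length:
            report.record(read.id, "fail_length")
            continue
        if max_homopolymer_run(seq) > params.max_homopolymer:
            report.record(read.id, "fail_homopolymer")
            continue
        if params.min_avg_quality > 0:
            if quals is None or len(quals) == 0:
                report.record(read.id, "fail_quality", "no quality scores supplied")
                continue
            if sum(quals) / len(quals) < params.min_avg_quality:
                report.record(read.id, "fail_quality")
                continue
        if not params.allow_ambiguities and any(c not in "ACGT" for c in seq):
            report.record(read.id, "fail_ambiguity")
            continue
        kept.append(AmpliconRead(id=read.id, nucleotides=seq, qualities=quals,
                                 barcode=read.barcode, site=read.site))
    if params.run_chimera_check and kept:
        seqs, counts, members = _dereplicate(kept)
        flags = detect_chimeras(list(zip(seqs, counts)),
                                params.chimera_score_threshold)
        chimeric_ids = set()
        for (seq, _), (is_chim, _score) in zip(zip(seqs, counts), flags):
            if is_chim:
                chimeric_ids.update(members[seq])
        still = []
        for read in kept:
            if read.id in chimeric_ids:
                report.record(read.id, "fail_chimera")
            else:
                still.append(read)
        kept = still
    for read in kept:
        report.record(read.id, "pass")
    return kept, report


def _dereplicate(reads: list[AmpliconRead]):
    """Unique sequences with abundances; ids kept for back-mapping."""
    members: dict[str, list[str]] = {}
    for read in reads:
        members.setdefault(read.nucleotides, []).append(read.id)
    # decreasing abundance, id-lexicographic tie-break (defines screen order)
    seqs = sorted(members, key=lambda s: (-len(members[s]), min(members[s])))
    counts = [len(members[s]) for s in seqs]
    return seqs, counts, members


#: Relative crossover points at which a query is split during scoring.
CROSSOVER_GRID = (0.25, 0.50, 0.75)

#: Candidate parents per query are capped at the most abundant accepted
#: sequences (standard top-N heuristic of de novo chimera detectors).
MAX_PARENTS = 20

#: Of those, only the closest few by full-length identity are tried as
#: chimera parents.
CANDIDATE_PARENTS = 4


def detect_chimeras(
    seqs_with_abundance: Sequence[tuple[str, int]],
    score_threshold: float = 0.05,
) -> list[tuple[bool, float]]:
    """Flag likely chimeras among dereplicated sequences.

    Queries are processed in decreasing abundance (the given order);
    candidate parents are previously processed sequences with abundance at
    least twice the query's.  For each crossover point on a small grid the
    query is split and the left/right segments are matched to their best
    *distinct* parents; the chimera score is
    ``min(segment identities) - best full-length single-parent identity``
    (identities as fractions).  A query is flagged when the score exceeds
    ``score_threshold``.  The most abundant sequence can never be flagged.

    Returns one ``(flagged, score)`` pair per input sequence.
    """
    def ident(a: str, b: str) -> float:
        # end-to-end semantics: overhangs count against identity, so a
        # partial perfect match cannot masquerade as full identity;
        # equal-length pairs take the gapless (Hamming) fast path
        if len(a) == len(b):
            return sum(x == y for x, y in zip(a, b)) / len(a)
        return percent_identity(a, b, "nucleotide", terminal_gaps="count") / 100.0

    results: list[tuple[bool, float]] = []
    accepted: list[tuple[str, int]] = []
    for seq, abund in seqs_with_abundance:
        parents = [(s, a) for s, a in accepted if a >= 2 * abund]
        if len(parents) > MAX_PARENTS:
            parents = sorted(parents, key=lambda p: -p[1])[:MAX_PARENTS]
        if len(parents) < 2:
            results.append((False, 0.0))
            accepted.append((seq, abund))
            continue
        full = [ident(seq, p) for p, _ in parents]
        # candidate chimera parents: closest few by full-length identity
        # (each true parent shares at least the crossover-side segment with
        # the query, so it ranks high); a small candidate set avoids the
        # upward selection bias of maximizing segment identity over many
        # unrelated sequences
        top = sorted(range(len(parents)), key=lambda i: -full[i])[:CANDIDATE_PARENTS]
        parents = [parents[i] for i in top]
        full = [full[i] for i in top]
        best_score = 0.0
        for u in CROSSOVER_GRID:
            cut = round(u * len(seq))
            left, right = seq[:cut], seq[cut:]
            if not left or not right:
                continue
            # parents are split at the same relative point, so each query
            # segment is compared against the corresponding parent segment
            lid = [ident(left, p[: round(u * len(p))]) for p, _ in parents]
            rid = [ident(right, p[round(u * len(p)):]) for p, _ in parents]
            li = int(max(range(len(parents)), key=lambda i: lid[i]))
            ri = int(max(range(len(parents)), key=lambda i: rid[i]))
            if li == ri:
                # chimera parents must be distinct: swap in the runner-up
                # on whichever side loses less
                alts_l = [i for i in range(len(parents)) if i != ri]
                alts_r = [i for i in range(len(parents)) if i != li]
                al = max(alts_l, key=lambda i: lid[i])
                ar = max(alts_r, key=lambda i: rid[i])
                if min(lid[al], rid[ri]) >= min(lid[li], rid[ar]):
                    li = al
                else:
                    ri = ar
            # score against the best of the *two candidate parents* only:
            # a genuine read's two best segment parents collapse onto its
            # nearest neighbour, driving the score to <= 0
            seg = min(lid[li], rid[ri])
            best_score = max(best_score, seg - max(full[li], full[ri]))
        flagged = best_score > score_threshold
        results.append((flagged, best_score))
        if not flagged:
            accepted.append((seq, abund))
    return results
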