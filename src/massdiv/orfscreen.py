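"""Translation and MasD-diagnostic screening of quality reads.

Quality-filtered amplicon reads are translated in the three forward frames
(bacterial code, translation table 11), the best frame is selected, and each
translated read is screened for (i) one of the six MasD-diagnostic motifs,
(ii) absence of internal stop codons, (iii) the catalytically active
cysteine at anchor position 477, and (iv) best-hit family assignment against
a labelled reference panel (MasD / NmsA / BssA / Pfl).  Reads failing any
check are accounted for in a per-rule rejection ledger.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

from . import anchors
from ._align import align_to_anchor_columns, percent_identity

__all__ = [
    "TranslatedRead",
    "ReferencePanel",
    "default_panel",
    "translate_frames",
    "select_frame",
    "find_motif",
    "check_catalytic_cysteine",
    "classify_family",
    "screen",
]

FAMILIES = ("MasD", "NmsA", "BssA", "Pfl")

#: Alignment identity below which a read is considered unalignable to the
#: anchor (the "twilight zone" floor for short protein fragments).
UNALIGNABLE_IDENTITY = 25.0


@dataclass
class TranslatedRead:
    """A read's protein translation plus its screening annotations."""

    read_id: str
    frame: int
    protein: str
    motif: str | None = None
    motif_position: int | None = None  # 0-based index into ``protein``
    has_internal_stop: bool = False
    catalytic_cys: str = "absent"  # present | absent | unalignable
    family: str = "unclassified"
    site: str | None = None


@dataclass
class ReferencePanel:
    """Labelled reference proteins with one designated anchor.

    ``members`` maps sequence name -> (family, protein).  The anchor supplies
    the coordinate system: its motif and catalytic-cysteine positions are
    1-based anchor coordinates, converted to 0-based indices only inside the
    operations that consume them.
    """

    members: dict[str, tuple[str, str]]
    anchor_name: str
    motif_position: int = anchors.MOTIF_POSITION_1BASED
    catalytic_position: int = anchors.CATALYTIC_POSITION_1BASED

    def __post_init__(self) -> None:
        if self.anchor_name not in self.members:
            raise ValueError(f"anchor {self.anchor_name!r} not in panel")
        families = {fam for fam, _ in self.members.values()}
        missing = set(FAMILIES) - families
        if missing:
            raise ValueError(f"panel missing families: {sorted(missing)}")

    @property
    def anchor(self) -> str:
        return self.members[self.anchor_name][1]


def default_panel() -> ReferencePanel:
    """Panel built from the synthetic anchor and off-target references."""
    members = {"HxN1_MasD_synthetic": ("MasD", anchors.ANCHOR_PROTEIN)}
    for fam, seq in anchors.OFFTARGET_PROTEINS.items():
        members[f"{fam}_synthetic"] = (fam, seq)
    return ReferencePanel(members=members, anchor_name="HxN1_MasD_synthetic")


def translate_frames(nt: str) -> list[str]:
    """Translate ``nt`` in frames 0, 1, 2 (forward strand, table 11).

    Internal stops are rendered as '*'; a trailing partial codon is dropped;
    ambiguity codes that do not resolve to a unique amino acid give 'X'.
    """
    if len(nt) < 3:
        raise ValueError("sequence shorter than one codon")
    nt = nt.upper().replace("U", "T")
    out = []
    for frame in range(3):
        sub = nt[frame : frame + 3 * ((len(nt) - frame) // 3)]
        if not sub:
            out.append("")
            continue
        try:
            prot = str(Seq(sub).translate(table=11))
        except Exception:
            # undecodable codons (rare ambiguity combinations) -> X per codon
            prot = "".join(
                _translate_codon(sub[i : i + 3]) for i in range(0, len(sub), 3)
            )
        out.append(prot)
    return out


def _translate_codon(codon: str) -> str:
    try:
        return str(Seq(codon).translate(table=11))
    except Exception:
        return "X"


def find_motif(
    protein: str, motif_set: Sequence[str] = anchors.MOTIFS
) -> tuple[str, int] | None:
    """Leftmost exact occurrence of any motif; ties broken by motif-set order."""
    if not protein:
        raise ValueError("empty protein")
    best: tuple[int, int] | None = None  # (position, motif index)
    for mi, motif in enumerate(motif_set):
        pos = protein.find(motif)
        if pos != -1 and (best is None or (pos, mi) < best):
            best = (pos, mi)
    if best is None:
        return None
    return motif_set[best[1]], best[0]


def select_frame(
    candidates: Sequence[str], motifs: Sequence[str] = anchors.MOTIFS
) -> tuple[int, str]:
    """Pick the reading frame of a read from its three translations.

    Priority: motif and no internal stop > motif > no internal stop >
    frame 0; ties go to the lowest frame index.
    """
    if len(candidates) != 3:
        raise ValueError("exactly three frame candidates required")

    def rank(prot: str) -> int:
        has_motif = any(m in prot for m in motifs)
        has_stop = "*" in prot
        if has_motif and not has_stop:
            return 0
        if has_motif:
            return 1
        if not has_stop:
            return 2
        return 3

    frame = min(range(3), key=lambda i: (rank(candidates[i]), i))
    return frame, candidates[frame]


def check_catalytic_cysteine(
    protein: str,
    anchor: str = anchors.ANCHOR_PROTEIN,
    catalytic_position: int = anchors.CATALYTIC_POSITION_1BASED,
) -> str:
    """Is the residue aligned to the anchor's catalytic column a cysteine?

    Returns 'present', 'absent', or 'unalignable' (alignment identity below
    25%). ``catalytic_position`` is 1-based in anchor coordinates.
    """
    col_map, identity = align_to_anchor_columns(anchor, protein)
    if identity < UNALIGNABLE_IDENTITY:
        return "unalignable"
    qpos = col_map[catalytic_position - 1]
    if qpos < 0 or qpos >= len(protein):
        return "absent"
    return "present" if protein[qpos] == "C" else "absent"


def classify_family(
    protein: str, panel: ReferencePanel, min_identity: float = 0.40
) -> str:
    """Family of the best-identity panel hit, or 'unclassified'.

    Ties between families at identical identity are resolved in the fixed
    order MasD > NmsA > BssA > Pfl.
    """
    if not panel.members:
        raise ValueError("empty reference panel")
    best_fam, best_ident = "unclassified", -1.0
    order = {fam: i for i, fam in enumerate(FAMILIES)}
    for name in sorted(panel.members):
        fam, seq = panel.members[name]
        # coverage-aware identity: a fragment must match over its whole
        # length, not just a lucky window of the reference
        ident = percent_identity(protein, seq, "protein",
                                 terminal_gaps="shorter") / 100.0
        if ident > best_ident or (
            ident == best_ident and order.get(fam, 99) < order.get(best_fam, 99)
        ):
            best_fam, best_ident = fam, ident
    return best_fam if best_ident >= min_identity else "unclassified"


@dataclass
class ScreenReport:
    """Per-rule rejection ledger for the translation screen."""

    counts: Counter = field(default_factory=Counter)
    verdicts: dict[str, str] = field(default_factory=dict)

    def record(self, read_id: str, verdict: str) -> None:
        self.counts[verdict] += 1
        self.verdicts[read_id] = verdict


def screen(
    reads: Iterable,
    panel: ReferencePanel | None = None,
    motifs: Sequence[str] = anchors.MOTIFS,
    min_identity: float = 0.40,
    classify: bool = True,
) -> tuple[list[TranslatedRead], ScreenReport]:
    """Translate QC-passed reads and keep confident MasD fragments.

    A read is accepted iff a motif is found AND there is no internal stop
    AND the catalytic cysteine is present AND (when ``classify``) the family
    call is MasD; the ledger records every read under its first failing
    rule (``no_motif``, ``stop_codon``, ``no_catalytic_cys``,
    ``wrong_family``, or ``pass``).

    ``reads`` are :class:`massdiv.readqc.AmpliconRead` objects whose
    nucleotides have been barcode- and primer-trimmed.
    """
    if panel is None:
        panel = default_panel()
    accepted: list[TranslatedRead] = []
    report = ScreenReport()
    for read in reads:
        frames = translate_frames(read.nucleotides)
        frame, protein = select_frame(frames, motifs)
        tr = TranslatedRead(read_id=read.id, frame=frame, protein=protein,
                            site=read.site)
        hit = find_motif(protein, motifs) if protein else None
        if hit is not None:
            tr.motif, tr.motif_position = hit
        tr.has_internal_stop = "*" in protein.rstrip("*")
        if tr.motif is None:
            report.record(read.id, "no_motif")
            continue
        if tr.has_internal_stop:
            report.record(read.id, "stop_codon")
            continue
        tr.catalytic_cys = check_catalytic_cysteine(
            protein, panel.anchor, panel.catalytic_position
        )
        if tr.catalytic_cys != "present":
            report.record(read.id, "no_catalytic_cys")
            continue
        if classify:
            tr.family = classify_family(protein, panel, min_identity)
            if tr.family != "MasD":
                report.record(read.id, "wrong_family")
                continue
        else:
            tr.family = "MasD"
        report.record(read.id, "pass")
        accepted.append(tr)
    return accepted, report
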