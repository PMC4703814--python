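"""Synthetic amplicon datasets with known ground truth.

This module emulates the statistical structure of a multi-site
functional-gene amplicon survey: a community of motif-bearing
protein-coding OTUs with lognormal abundances spread over several sites,
sequenced with 454-style errors (substitutions plus homopolymer-weighted
indels), PCR chimeras, and off-target reads co-amplified by the degenerate
primers.  Every emitted read carries a truth record (site, OTU, chimera /
off-target flags, frame), so downstream stages can be scored against known
answers.

It also simulates paired 16S/marker-protein strain sets lying on a
configurable linear identity-identity relation, the input of the
threshold-calibration procedure.

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import anchors
from .orfscreen import find_motif

__all__ = [
    "CommunitySpec",
    "ErrorModel",
    "StrainPairSpec",
    "evolve_protein_family",
    "default_references",
    "back_translate",
    "generate_dataset",
    "simulate_strain_pairs",
]


# --------------------------------------------------------------------------
# Specifications

@dataclass
class CommunitySpec:
    """Shape of the simulated multi-site community.

    Defaults mirror a 12-site seep survey at desk scale: 40 OTUs with
    lognormal abundances (sigma = 1 on the log scale), 200 reads per site,
    5% cosmopolitan OTUs (present everywhere), and the remaining OTUs each
    occupying half of the sites.
    """

    n_sites: int = 12
    n_otus: int = 40
    abundance_model: str = "lognormal"
    abundance_params: dict = field(default_factory=lambda: {"mean": 0.0, "sigma": 1.0})
    reads_per_site: int = 200
    cosmopolitan_fraction: float = 0.05
    site_overlap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_otus < 1 or self.reads_per_site < 1:
            raise ValueError("n_sites, n_otus and reads_per_site must be >= 1")
        for name in ("cosmopolitan_fraction", "site_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.abundance_model not in ("lognormal", "uniform", "geometric"):
            raise ValueError(f"unknown abundance model {self.abundance_model!r}")


@dataclass
class ErrorModel:
    """Per-read error process in the 454 idiom.

    Substitutions are rare; indels concentrate in homopolymer runs (the
    behaviour that motivates the max-homopolymer quality filter).  Phred
    qualities are drawn independently of the planted errors from a
    truncated normal clamped to [2, 40].
    """

    substitution_rate: float = 0.001
    indel_rate: float = 0.0005
    homopolymer_indel_multiplier: float = 8.0
    chimera_fraction: float = 0.05
    offtarget_fraction: float = 0.10
    quality_mean: float = 33.0
    quality_sd: float = 4.0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate", "chimera_fraction",
                     "offtarget_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.homopolymer_indel_multiplier < 1.0:
            raise ValueError("homopolymer_indel_multiplier must be >= 1")

    @classmethod
    def none(cls) -> "ErrorModel":
        """An error-free model (clean reads, no chimeras, no off-targets)."""
        return cls(substitution_rate=0.0, indel_rate=0.0,
                   chimera_fraction=0.0, offtarget_fraction=0.0)


@dataclass
class StrainPairSpec:
    """Strain set whose protein identity is linearly coupled to 16S identity.

    ``slope``/``intercept`` are on the percent-identity scale (protein % =
    intercept + slope * 16S %); ``noise_sd`` is the standard deviation of
    the Gaussian scatter around that line, in identity percentage points.
    ``max_16s_divergence`` sets how far the most divergent strain sits from
    the anchor (as a fraction).
    """

    n_strains: int = 15
    slope: float = 2.08
    intercept: float = -109.3
    noise_sd: float = 1.0
    max_16s_divergence: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 3:
            raise ValueError("n_strains must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.slope <= 0:
            raise ValueError("slope must be positive (model assumes positive coupling)")


# --------------------------------------------------------------------------
# Reference evolution and back-translation

def evolve_protein_family(
    ancestor: str,
    divergences: list[float],
    seed: int = 0,
    catalytic_position: int | None = None,
) -> list[str]:
    """Evolve one reference protein per requested divergence (star topology).

    Substitutions never touch the diagnostic motif or the catalytic
    cysteine; the number of substituted positions is deterministic,
    ``round(d * len(ancestor))``.  ``catalytic_position`` is the 0-based
    index of the catalytic cysteine within ``ancestor``; by default the
    first cysteine downstream of the motif is used.
    """
    hit = find_motif(ancestor)
    if hit is None:
        raise ValueError("ancestor lacks a diagnostic motif (FECIR/FECIK/"
                         "FECQR/FECVR/FDCIR/FDNIA)")
    motif, mpos = hit
    if catalytic_position is None:
        catalytic_position = ancestor.find("C", mpos + len(motif))
        if catalytic_position == -1:
            raise ValueError("ancestor lacks a catalytic cysteine downstream "
                             "of the motif")
    if ancestor[catalytic_position] != "C":
        raise ValueError(
            f"residue at catalytic position {catalytic_position} is "
            f"{ancestor[catalytic_position]!r}, not the catalytic cysteine"
        )
    protected = set(range(mpos, mpos + len(motif))) | {catalytic_position}
    mutable = np.array(sorted(set(range(len(ancestor))) - protected))
    rng = np.random.default_rng(seed)
    out = []
    for d in divergences:
        if not 0.0 <= d <= 0.6:
            raise ValueError("divergences must be in [0, 0.6]")
        k = round(d * len(ancestor))
        if k > len(mutable):
            raise ValueError(f"divergence {d} exceeds mutable positions")
        seq = list(ancestor)
        for pos in rng.choice(mutable, size=k, replace=False):
            choices = [a for a in anchors.AMINO_ACIDS if a != seq[pos]]
            seq[pos] = choices[rng.integers(len(choices))]
        out.append("".join(seq))
    return out


def default_references(n_otus: int, seed: int = 0) -> list[str]:
    """Evolve ``n_otus`` well-separated OTU references from the anchor fragment.

    Radial divergences are spread over [0.06, 0.45]; on a star topology the
    pairwise divergence between any two references is approximately the sum
    of their radii, so every pair sits far above the 4% species threshold.
    """
    divergences = list(np.linspace(0.06, 0.45, n_otus))
    cat = anchors.CATALYTIC_POSITION_1BASED - 1 - anchors.FRAGMENT_START
    return evolve_protein_family(anchors.ANCHOR_FRAGMENT, divergences, seed,
                                 catalytic_position=cat)


def _codon_map() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[11]
    out: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    return out


_CODONS = _codon_map()


def back_translate(
    protein: str,
    rng: np.random.Generator,
    codon_weights: dict[str, dict[str, float]] | None = None,
    max_homopolymer: int | None = 8,
    context: tuple[str, str] = ("", ""),
) -> str:
    """Back-translate a protein with seeded synonymous codon choice.

    By default synonymous codons are drawn uniformly; ``codon_weights``
    (aa -> codon -> weight) switches to a weighted codon-usage model.
    When ``max_homopolymer`` is set, synonymous choices are repaired so the
    final construct contains no homopolymer run longer than that (real
    coding sequences essentially never contain 9-base runs);
    ``context=(prefix, suffix)`` supplies the flanking bases of the final
    construct so junction runs are capped too.
    """
    codons = []
    for aa in protein:
        options = _CODONS.get(aa)
        if options is None:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        if codon_weights and aa in codon_weights:
            w = np.array([codon_weights[aa].get(c, 0.0) for c in options])
            p = w / w.sum()
            codons.append(options[rng.choice(len(options), p=p)])
        else:
            codons.append(options[rng.integers(len(options))])
    if max_homopolymer is not None:
        _repair_homopolymers(codons, protein, context, max_homopolymer, rng)
    return "".join(codons)


def _longest_run(seq: str) -> tuple[int, int]:
    """(length, start) of the longest homopolymer run."""
    best, best_start = 1, 0
    run, start = 1, 0
    for i in range(1, len(seq)):
        if seq[i] == seq[i - 1]:
            run += 1
        else:
            run, start = 1, i
        if run > best:
            best, best_start = run, start
    return best, best_start


def _repair_homopolymers(codons: list[str], protein: str,
                         context: tuple[str, str], cap: int,
                         rng: np.random.Generator) -> None:
    """Swap synonymous codons until no run in the construct exceeds ``cap``.

    Every amino acid has either synonymous codons differing in the third
    base or a codon whose own bases break a run, so a long run can always
    be interrupted by re-choosing one of the codons it spans.
    """
    prefix, suffix = context
    for _ in range(10 * len(codons) + 10):
        construct = prefix + "".join(codons) + suffix
        run, start = _longest_run(construct)
        if run <= cap:
            return
        lo, hi = start - len(prefix), start - len(prefix) + run
        touched = [i for i in range(len(codons))
                   if 3 * i < hi and 3 * i + 3 > lo]
        window = (max(0, start - 1), start + run + 1)
        improved = False
        for ci in touched:
            options = [c for c in _CODONS[protein[ci]] if c != codons[ci]]
            rng.shuffle(options)
            for alt in options:
                old = codons[ci]
                codons[ci] = alt
                local = (prefix + "".join(codons) + suffix)[window[0]:window[1]]
                if _longest_run(local)[0] < run:  # this run was broken
                    improved = True
                    break
                codons[ci] = old
            if improved:
                break
        if not improved:  # pragma: no cover - flanks may pin a run at cap+
            return


# --------------------------------------------------------------------------
# Read generation

def _site_names(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def _make_barcodes(sites: list[str], rng: np.random.Generator) -> dict[str, str]:
    barcodes: dict[str, str] = {}
    used: set[str] = set()
    for site in sites:
        while True:
            bc = "".join("ACGT"[i] for i in rng.integers(0, 4, size=8))
            if bc not in used:
                used.add(bc)
                barcodes[site] = bc
                break
    return barcodes


def _abundances(spec: CommunitySpec, rng: np.random.Generator) -> np.ndarray:
    p = spec.abundance_params
    if spec.abundance_model == "lognormal":
        ab = rng.lognormal(p.get("mean", 0.0), p.get("sigma", 1.0), spec.n_otus)
    elif spec.abundance_model == "uniform":
        ab = rng.uniform(p.get("low", 0.5), p.get("high", 1.5), spec.n_otus)
    else:  # geometric rank-abundance series
        ratio = p.get("ratio", 0.9)
        ab = ratio ** np.arange(spec.n_otus)
        rng.shuffle(ab)
    return ab


def _apply_errors(nt: str, error: ErrorModel, rng: np.random.Generator) -> str:
    if error.substitution_rate <= 0 and error.indel_rate <= 0:
        return nt
    arr = np.frombuffer(nt.encode(), dtype="S1").copy()
    n = len(arr)
    # substitutions
    if error.substitution_rate > 0:
        mask = rng.random(n) < error.substitution_rate
        for i in np.where(mask)[0]:
            base = arr[i].decode()
            others = [b for b in "ACGT" if b != base]
            arr[i] = others[rng.integers(3)].encode()
    seq = arr.tobytes().decode()
    # indels, homopolymer-weighted: a base sitting at the end of a run of
    # >= 3 identical bases is indel-prone by the configured multiplier
    if error.indel_rate > 0:
        chars = np.frombuffer(seq.encode(), dtype="S1")
        run = np.ones(len(chars))
        for i in range(1, len(chars)):
            run[i] = run[i - 1] + 1 if chars[i] == chars[i - 1] else 1
        prob = np.where(run >= 3,
                        error.indel_rate * error.homopolymer_indel_multiplier,
                        error.indel_rate)
        prob = np.clip(prob, 0.0, 1.0)
        hits = np.where(rng.random(len(chars)) < prob)[0]
        if hits.size:
            out = []
            prev = 0
            for i in hits:
                out.append(seq[prev:i])
                if rng.random() < 0.5:
                    out.append(seq[i] * 2)  # insertion: duplicate the base
                # else deletion: drop the base
                prev = i + 1
            out.append(seq[prev:])
            seq = "".join(out)
    return seq


def _qualities(n: int, error: ErrorModel, rng: np.random.Generator) -> list[int]:
    q = rng.normal(error.quality_mean, error.quality_sd, size=n)
    return [int(v) for v in np.clip(np.rint(q), 2, 40)]


def generate_dataset(
    spec: CommunitySpec,
    error: ErrorModel,
    references: list[str],
    offtarget_proteins: list[str] | None = None,
    barcodes: dict[str, str] | None = None,
):
    """Simulate barcoded amplicon reads plus a per-read truth table.

    Per site, OTU read counts are drawn from the abundance model and
    multinomial-sampled to ``reads_per_site``; each read is
    barcode + forward primer + back-translated coding sequence +
    reverse-complemented reverse primer, with the error model applied.
    A deterministic ``round(fraction * reads_per_site)`` count of reads per
    site is replaced by chimeras (two-parent joins with a crossover point
    uniform in the central 60% of the read) and off-target reads
    (back-translated fragments of the NmsA/BssA-like panel).

    Returns ``(reads, truth)`` where ``reads`` is a list of
    :class:`massdiv.readqc.AmpliconRead` and ``truth`` a DataFrame indexed
    by read id with columns site, otu, is_chimera, is_offtarget, frame.
    """
    from .readqc import AmpliconRead  # deferred: readqc imports nothing from here

    if not references:
        raise ValueError("references must be non-empty")
    if len(references) < spec.n_otus:
        raise ValueError("need at least spec.n_otus reference proteins")
    rng = np.random.default_rng(spec.seed)
    sites = _site_names(spec.n_sites)
    if barcodes is None:
        barcodes = _make_barcodes(sites, rng)

    if offtarget_proteins is None:
        offtarget_proteins = [
            anchors.OFFTARGET_PROTEINS["NmsA"][100:226],
            anchors.OFFTARGET_PROTEINS["BssA"][100:226],
        ]

    fwd = anchors.FORWARD_PRIMER_REALIZED
    rev_rc = _revcomp(anchors.REVERSE_PRIMER_REALIZED)
    # one seeded back-translation per reference: reads of an OTU share a
    # CDS; junction context keeps the whole construct homopolymer-clean
    ref_cds = [back_translate(p, rng, context=(fwd, rev_rc))
               for p in references[: spec.n_otus]]
    off_cds = [back_translate(p, rng, context=(fwd, rev_rc))
               for p in offtarget_proteins]

    abundance = _abundances(spec, rng)
    n_cosmo = round(spec.cosmopolitan_fraction * spec.n_otus)
    cosmo = set(np.argsort(abundance)[::-1][:n_cosmo])
    k_sites = max(1, round(spec.site_overlap * spec.n_sites))
    presence = np.zeros((spec.n_sites, spec.n_otus), dtype=bool)
    for o in range(spec.n_otus):
        if o in cosmo:
            presence[:, o] = True
        else:
            presence[rng.choice(spec.n_sites, size=k_sites, replace=False), o] = True

    reads = []
    truth_rows = []
    for si, site in enumerate(sites):
        weights = abundance * presence[si]
        if weights.sum() == 0:  # pragma: no cover - presence guarantees >=1
            weights = abundance
        counts = rng.multinomial(spec.reads_per_site, weights / weights.sum())
        otu_of_read = np.repeat(np.arange(spec.n_otus), counts)
        rng.shuffle(otu_of_read)

        n_off = round(error.offtarget_fraction * spec.reads_per_site)
        n_chim = round(error.chimera_fraction * spec.reads_per_site)
        special = rng.choice(spec.reads_per_site, size=min(n_off + n_chim,
                                                           spec.reads_per_site),
                             replace=False)
        off_idx = set(special[:n_off])
        chim_idx = set(special[n_off:n_off + n_chim])

        # ordinary reads first; chimeras join two of them afterwards
        site_nts: list[str | None] = [None] * spec.reads_per_site
        for j in range(spec.reads_per_site):
            if j in chim_idx:
                continue
            if j in off_idx:
                cds = off_cds[rng.integers(len(off_cds))]
            else:
                cds = ref_cds[otu_of_read[j]]
            nt = barcodes[site] + fwd + cds + rev_rc
            site_nts[j] = _apply_errors(nt, error, rng)
        normal = [j for j in range(spec.reads_per_site)
                  if j not in chim_idx and j not in off_idx]
        for j in sorted(chim_idx):
            if len(normal) >= 2:
                a, b = rng.choice(normal, size=2, replace=False)
            else:  # degenerate tiny datasets
                a = b = normal[0] if normal else None
            if a is None:
                site_nts[j] = barcodes[site] + fwd + ref_cds[0] + rev_rc
            else:
                pa, pb = site_nts[a], site_nts[b]
                u = rng.uniform(0.2, 0.8)  # crossover in the central 60%
                site_nts[j] = pa[: round(u * len(pa))] + pb[round(u * len(pb)):]

        for j in range(spec.reads_per_site):
            rid = f"{site}_r{j:05d}"
            nt = site_nts[j]
            reads.append(AmpliconRead(
                id=rid, nucleotides=nt,
                qualities=_qualities(len(nt), error, rng),
            ))
            truth_rows.append({
                "read_id": rid,
                "site": site,
                "otu": -1 if (j in off_idx or j in chim_idx)
                       else int(otu_of_read[j]),
                "is_chimera": j in chim_idx,
                "is_offtarget": j in off_idx,
                "frame": 0,
            })

    truth = pd.DataFrame(truth_rows).set_index("read_id")
    truth.attrs["barcodes"] = barcodes
    return reads, truth


def _revcomp(nt: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return nt.translate(comp)[::-1]


# --------------------------------------------------------------------------
# Calibration strain pairs

def simulate_strain_pairs(
    spec: StrainPairSpec,
    anchor_protein: str = anchors.ANCHOR_PROTEIN,
    anchor_16s: str = anchors.ANCHOR_16S,
):
    """Simulate strains whose protein identity tracks 16S identity linearly.

    Strains sit on a star phylogeny around the anchors.  Radial 16S
    divergences are spread evenly up to ``max_16s_divergence``; each
    strain's protein divergence is chosen so that expected pairwise protein
    identity follows ``intercept + slope * s16`` with Gaussian scatter of
    ``noise_sd`` percentage points.

    Returns a list of :class:`massdiv.calibrate.StrainRecord`.
    """
    from .calibrate import StrainRecord

    if len(anchor_16s) < 300:
        raise ValueError("16S anchor must be >= 300 nt")
    if len(anchor_protein) < 100:
        raise ValueError("protein anchor must be >= 100 aa")
    rng = np.random.default_rng(spec.seed)
    d16 = np.linspace(0.0, spec.max_16s_divergence, spec.n_strains)
    # per-strain protein divergence making the *pairwise* relation linear:
    # s_prot(pair) = intercept + slope * s16(pair) on a star topology where
    # pairwise divergence is the sum of the two radial divergences
    offset = (100.0 - spec.intercept - 100.0 * spec.slope) / 2.0
    noise = rng.normal(0.0, spec.noise_sd / np.sqrt(2.0), spec.n_strains)
    dprot = spec.slope * d16 * 100.0 + offset + noise
    dprot = np.clip(dprot, 0.0, 60.0) / 100.0

    records = []
    lp, l16 = len(anchor_protein), len(anchor_16s)
    for i in range(spec.n_strains):
        prot = _mutate(anchor_protein, round(dprot[i] * lp), anchors.AMINO_ACIDS, rng)
        s16 = _mutate(anchor_16s, round(d16[i] * l16), "ACGT", rng)
        records.append(StrainRecord(strain_id=f"strain{i + 1:02d}",
                                    protein=prot, s16=s16))
    return records


def _mutate(seq: str, k: int, alphabet: str, rng: np.random.Generator) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=k, replace=False):
        choices = [a for a in alphabet if a != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)
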