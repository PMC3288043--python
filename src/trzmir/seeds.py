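"""miRNA seed-site scanning, seed families and reporter-mutant construction.

The seed is nucleotides 2-8 of the mature miRNA (7 nt; for the miR-30 family
this is GUAAACA).  A target site on an mRNA 3'UTR is the reverse complement
of (part of) the seed, read on the sense strand, graded by the canonical
site-type taxonomy:

========  ============================================================
8mer      reverse complement of nt 2-8, followed by an A (opposite nt 1)
7mer-m8   reverse complement of nt 2-8
7mer-A1   reverse complement of nt 2-7, followed by an A
6mer      reverse complement of nt 2-7
========  ============================================================

Only the maximal site type is reported at a locus: lower-grade matches whose
interval lies inside an accepted higher-grade site are suppressed.
Coordinates are 0-based half-open on the UTR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, FormatError

_RNA = set("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
# site types strongest first; used for suppression precedence
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def _to_rna(seq: str, what: str) -> str:
    s = seq.upper().replace("T", "U")
    if set(s) - _RNA:
        raise FormatError(f"{what} contains invalid characters: {sorted(set(s) - _RNA)}")
    return s


def reverse_complement(rna: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(rna))


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, 5'->3'."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _to_rna(self.sequence, f"miRNA {self.name}"))
        if len(self.sequence) < 18:
            raise FormatError(f"miRNA {self.name} shorter than 18 nt")

    @property
    def seed(self) -> str:
        """Nucleotides 2-8 (7 nt)."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class UTRSeq:
    """A 3'UTR sequence; DNA and RNA encodings are unified to RNA internally."""

    gene: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _to_rna(self.sequence, f"UTR {self.gene}"))


@dataclass(frozen=True)
class SeedSite:
    """A seed-match interval on a UTR, 0-based half-open."""

    start: int
    end: int
    site_type: str
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ContractError(f"unknown site type {self.site_type!r}")
        if self.end - self.start != {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[
            self.site_type
        ]:
            raise ContractError("site span inconsistent with its type")

    def as_1based(self) -> tuple[int, int]:
        """Inclusive 1-based coordinates for human-readable reports."""
        return self.start + 1, self.end


def site_motifs(mirna: MatureMiRNA) -> dict[str, str]:
    """Target-site motifs (RNA, sense strand of the UTR) for each site type."""
    seed28 = mirna.sequence[1:8]  # nt 2-8
    seed27 = mirna.sequence[1:7]  # nt 2-7
    m7m8 = reverse_complement(seed28)
    m6 = reverse_complement(seed27)
    return {
        "8mer": m7m8 + "A",
        "7mer-m8": m7m8,
        "7mer-A1": m6 + "A",
        "6mer": m6,
    }


def find_seed_sites(mirna: MatureMiRNA, utr: UTRSeq) -> list[SeedSite]:
    """All maximal seed-match sites of ``mirna`` on the sense strand of ``utr``.

    Candidates of every type are enumerated; going from strongest to weakest
    type, a candidate is kept unless its interval is contained in an already
    accepted site of a higher grade.  Sites are returned sorted by start.
    """
    seq = utr.sequence
    motifs = site_motifs(mirna)
    accepted: list[SeedSite] = []
    for stype in SITE_TYPES:
        motif = motifs[stype]
        width = len(motif)
        pos = seq.find(motif)
        while pos != -1:
            start, end = pos, pos + width
            contained = any(
                s.start <= start and end <= s.end for s in accepted
            )
            if not contained:
                accepted.append(SeedSite(start, end, stype, seq[start:end]))
            pos = seq.find(motif, pos + 1)
    return sorted(accepted, key=lambda s: (s.start, s.end))


_TRANSVERSION = {"A": "C", "C": "A", "G": "U", "U": "G"}


@dataclass
class MutatedConstruct:
    """A UTR with selected seed sites disrupted by point transversions."""

    sequence: str
    edits: list[tuple[int, str, str]] = field(default_factory=list)
    disrupted_sites: list[SeedSite] = field(default_factory=list)


def mutate_seed_sites(
    utr: UTRSeq,
    sites: list[SeedSite],
    mirna: MatureMiRNA,
    rng_seed: int = 0,
) -> MutatedConstruct:
    """Disrupt the given seed sites with 3 transversions each.

    The substituted positions lie in the seed-pairing region of each site (the
    reverse complement of miRNA nt 2-8, or nt 2-7 for 6mer-grade sites).  The
    construct is deterministic given ``rng_seed``; positions are re-drawn until
    rescanning the mutated sequence finds no site of any type overlapping a
    disrupted locus, while sites not selected for mutation are preserved.
    """
    seq = list(utr.sequence)
    for site in sites:
        if utr.sequence[site.start : site.end] != site.sequence or site.sequence == "":
            raise ContractError(f"stale site coordinates [{site.start}, {site.end})")

    rng = np.random.default_rng(rng_seed)
    edits: list[tuple[int, str, str]] = []
    for site in sites:
        # seed-pairing region: the match to nt 2-7/2-8, excluding the A
        # opposite nt 1 that closes 7mer-A1/8mer sites
        core_end = site.end - (1 if site.site_type in ("8mer", "7mer-A1") else 0)
        core = list(range(site.start, core_end))
        for attempt in range(20):
            positions = sorted(rng.choice(core, size=min(3, len(core)), replace=False))
            trial = list(seq)
            trial_edits = []
            for p in positions:
                old = trial[p]
                new = _TRANSVERSION[old]
                trial[p] = new
                trial_edits.append((p, old, new))
            rescanned = find_seed_sites(mirna, UTRSeq(utr.gene, "".join(trial)))
            if not any(s.start < site.end and site.start < s.end for s in rescanned):
                seq = trial
                edits.extend(trial_edits)
                break
        else:  # pragma: no cover - 3 transversions always break a <=8 nt motif
            raise ContractError(f"could not disrupt site at [{site.start}, {site.end})")
    return MutatedConstruct(sequence="".join(seq), edits=edits, disrupted_sites=list(sites))


def seed_family(mirnas: list[MatureMiRNA]) -> dict[str, list[str]]:
    """Partition miRNA names by identical seed (nt 2-8)."""
    families: dict[str, list[str]] = {}
    for m in mirnas:
        families.setdefault(m.seed, []).append(m.name)
    return families
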