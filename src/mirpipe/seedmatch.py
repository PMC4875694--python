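"""Seed-complementarity miRNA target-site prediction.

A mature miRNA binds its target chiefly through its seed, nucleotides 2-7
(optionally extended to 8) counted 5'->3' along the miRNA. On the mRNA
3'UTR this corresponds to the reverse complement of the seed (after U->T),
optionally flanked by a match to miRNA position 8 on the 5' side and an
adenosine opposite miRNA position 1 on the 3' side. The canonical site
classes, weakest to strongest:

* ``6mer``     — reverse complement of seed 2-7 only
* ``7mer-a1``  — 6mer followed by an A in the UTR
* ``7mer-m8``  — reverse complement of seed 2-8
* ``8mer``     — reverse complement of seed 2-8 followed by an A

Scanning anchors on every occurrence of the 6mer core in the UTR and
reports exactly one site per anchor, classified as the strongest applicable
class. Only perfect Watson-Crick complementarity is considered: no G:U
wobble, no 3'-compensatory pairing, no context scoring. ``N`` in a UTR
never matches any motif position.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: site classes ordered weakest -> strongest
SITE_TYPES = ("6mer", "7mer-a1", "7mer-m8", "8mer")
SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}

_RC = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A", "N": "N"}


def reverse_complement_to_dna(rna: str) -> str:
    """Reverse complement of an RNA (or DNA) string, in the DNA alphabet."""
    return "".join(_RC[c] for c in reversed(rna.upper()))


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence (RNA alphabet, 5'->3') with its seeds."""

    mirna_id: str
    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 8:
            raise ValidationError(
                f"{self.mirna_id}: mature miRNA must be >=8 nt, got {len(seq)}"
            )
        bad = set(seq) - set("ACGUN")
        if bad:
            raise ValidationError(
                f"{self.mirna_id}: non-RNA character(s) {sorted(bad)}"
            )

    @property
    def seed6(self) -> str:
        """miRNA positions 2-7 (1-based)."""
        return self.sequence[1:7]

    @property
    def seed7(self) -> str:
        """miRNA positions 2-8 (1-based)."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class SeedSite:
    """One classified seed-match site in a 3'UTR (0-based half-open offsets)."""

    mirna_id: str
    transcript_id: str
    utr_start: int
    utr_end: int
    site_type: str
    motif: str


def site_motifs(mirna: MatureMiRNA) -> dict[str, str]:
    """DNA motifs (as found in the 3'UTR, 5'->3') for each site class."""
    if "N" in mirna.sequence[:8]:
        raise ValidationError(f"{mirna.mirna_id}: ambiguous seed (N in positions 1-8)")
    core = reverse_complement_to_dna(mirna.seed6)
    ext = reverse_complement_to_dna(mirna.seed7)
    return {
        "6mer": core,
        "7mer-a1": core + "A",
        "7mer-m8": ext,
        "8mer": ext + "A",
    }


def scan_utr(mirna: MatureMiRNA, transcript_id: str, utr: str) -> list[SeedSite]:
    """Find and classify all seed sites of one miRNA in one 3'UTR.

    Anchors are occurrences of the 6mer core; each anchor yields exactly one
    site of the strongest applicable class. Overlapping anchors are reported
    independently. Scanning is case-insensitive.
    """
    utr = utr.upper()
    bad = set(utr) - set("ACGTN")
    if bad:
        raise ValidationError(
            f"{transcript_id}: non-DNA character(s) {sorted(bad)} in UTR"
        )
    motifs = site_motifs(mirna)
    core = motifs["6mer"]
    m8_char = motifs["7mer-m8"][0]  # complement of miRNA position 8
    sites: list[SeedSite] = []
    pos = utr.find(core)
    while pos != -1:
        has_m8 = pos > 0 and utr[pos - 1] == m8_char
        has_a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        if has_m8 and has_a1:
            start, site_type = pos - 1, "8mer"
        elif has_m8:
            start, site_type = pos - 1, "7mer-m8"
        elif has_a1:
            start, site_type = pos, "7mer-a1"
        else:
            start, site_type = pos, "6mer"
        end = start + len(motifs[site_type])
        sites.append(
            SeedSite(
                mirna_id=mirna.mirna_id,
                transcript_id=transcript_id,
                utr_start=start,
                utr_end=end,
                site_type=site_type,
                motif=utr[start:end],
            )
        )
        pos = utr.find(core, pos + 1)
    return sites


def predict_targets(
    mirnas: list[MatureMiRNA],
    utrs: dict[str, str],
    min_site_type: str = "6mer",
) -> list[SeedSite]:
    """Scan every (miRNA, UTR) pair, keeping sites at or above a stringency.

    Output is deterministically ordered by (mirna_id, transcript_id,
    utr_start).
    """
    if not mirnas or not utrs:
        raise ValidationError("empty miRNA or UTR set")
    if min_site_type not in SITE_RANK:
        raise ValidationError(f"unknown site type {min_site_type!r}")
    min_rank = SITE_RANK[min_site_type]
    sites = [
        s
        for m in mirnas
        for tid, utr in utrs.items()
        for s in scan_utr(m, tid, utr)
        if SITE_RANK[s.site_type] >= min_rank
    ]
    sites.sort(key=lambda s: (s.mirna_id, s.transcript_id, s.utr_start))
    return sites


def best_site_types(sites: list[SeedSite]) -> dict[tuple[str, str], str]:
    """Strongest site class per (mirna_id, transcript_id) pair."""
    best: dict[tuple[str, str], str] = {}
    for s in sites:
        key = (s.mirna_id, s.transcript_id)
        if key not in best or SITE_RANK[s.site_type] > SITE_RANK[best[key]]:
            best[key] = s.site_type
    return best


def write_site_table(sites: list[SeedSite], path) -> None:
    """Write sites as TSV (mirna_id, transcript_id, offsets, type, motif)."""
    with open(path, "w") as fh:
        fh.write("mirna_id\ttranscript_id\tutr_start\tutr_end\tsite_type\tmotif\n")
        for s in sites:
            fh.write(
                f"{s.mirna_id}\t{s.transcript_id}\t{s.utr_start}\t{s.utr_end}\t"
                f"{s.site_type}\t{s.motif}\n"
            )
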