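"""Frameshift heptamer scanning and dual-ORF gene models.

+1 programmed ribosomal frameshifting in *Saccharomyces cerevisiae* occurs at
7-nt "shift sites" spanning the P-site codon and the two overlapping A-site
codons (0-frame and +1-frame).  Writing ``_`` for 0-frame codon boundaries and
``.`` for +1-frame boundaries, the canonical Ty1 site is ``CUU_A.GG_C``: a
ribosome that has decoded CUU in the P site slips one nucleotide forward and
next decodes GGC instead of AGG.  A gene using such a site encodes a single
trans-frame protein from two overlapping ORFs: a 0-frame ORF carrying the
heptamer and a +1-frame ORF read from the fourth heptamer base onward.

This module locates heptamer occurrences in-frame with an annotated ORF,
assembles the corresponding dual-ORF gene model, constructs the "fused"
in-frame coding sequence (the single-nucleotide deletion that joins the two
frames, e.g. CTTAGGC -> CTTGGC), and predicts the trans-frame protein.

Coordinates are 0-based half-open throughout; GFF3 I/O converts to and from
the 1-based closed convention.  RNA input (U) is normalised to DNA (T).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_VALID_SEQ = re.compile(r"^[ACGTN]*$")


class HeptamerScanError(ValueError):
    """Invalid sequence or site handed to the scanner."""


class OpenModelError(ValueError):
    """A dual-ORF model could not be closed (a required stop codon is missing)."""


def normalize_sequence(sequence: str) -> str:
    """Uppercase and map RNA (U) onto the DNA alphabet; reject anything but ACGTN.

    N is accepted as an unknown base but never matches a heptamer.
    """
    seq = sequence.upper().replace("U", "T")
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise HeptamerScanError(f"sequence contains non-ACGTU characters: {bad}")
    return seq


# ---------------------------------------------------------------------------
# Heptamer motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeptamerMotif:
    """A 7-nt +1 frameshift site.

    The heptamer decomposes as ``p_codon`` (nt 1-3, the P-site codon),
    ``a0_codon`` (nt 4-6, the 0-frame A-site codon) and ``a1_codon`` (nt 5-7,
    the +1-frame A-site codon).  ``repairing_allowed`` records whether the
    P-site tRNA can re-pair with the overlapping +1 codon (true for the
    CUU-type sites, false for the GCG-type sites).
    """

    name: str
    dna: str
    repairing_allowed: bool

    def __post_init__(self) -> None:
        if len(self.dna) != 7 or set(self.dna) - set("ACGT"):
            raise ValueError(f"heptamer must be 7 ACGT letters, got {self.dna!r}")

    @property
    def p_codon(self) -> str:
        return self.dna[0:3]

    @property
    def a0_codon(self) -> str:
        return self.dna[3:6]

    @property
    def a1_codon(self) -> str:
        return self.dna[4:7]


#: The four +1 frameshift heptamers known in S. cerevisiae.  The CUU P-site
#: sites (Ty1/ABP140/YFS1/LLP1 and EST3) permit P-site tRNA re-pairing in the
#: +1 frame; the GCG P-site sites (Ty3 and the OAZ1 antizyme site) do not.
#: Note the OAZ1 heptamer contains a 0-frame stop codon (TGA) as its A0 codon.
MOTIFS: dict[str, HeptamerMotif] = {
    m.name: m
    for m in (
        HeptamerMotif("Ty1-type", "CTTAGGC", repairing_allowed=True),
        HeptamerMotif("EST3-type", "CTTAGTT", repairing_allowed=True),
        HeptamerMotif("Ty3-type", "GCGAGTT", repairing_allowed=False),
        HeptamerMotif("OAZ1-type", "GCGTGAC", repairing_allowed=False),
    )
}

_MOTIF_BY_DNA: dict[str, HeptamerMotif] = {m.dna: m for m in MOTIFS.values()}


# ---------------------------------------------------------------------------
# Sites and models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameshiftSite:
    """A heptamer occurrence anchored to an ORF.

    ``start`` is the 0-based offset of the heptamer's first base; ``orf_start``
    is the 0-based position of the anchoring ATG.  ``frame`` is the phase of
    the heptamer relative to that anchor (0 for a codon-aligned site).
    """

    seq_id: str
    start: int
    motif: HeptamerMotif
    orf_start: int = 0

    @property
    def frame(self) -> int:
        return (self.start - self.orf_start) % 3


@dataclass(frozen=True)
class DualOrfGeneModel:
    """Two overlapping ORFs joined by a +1 frameshift site.

    ``orf0_start``/``orf0_end`` bound the 0-frame ORF (half-open, stop codon
    included); ``orf1_end`` is the end of the +1-frame ORF, whose codons run
    from ``site.start + 4`` in steps of three up to and including the first
    +1-frame stop.
    """

    seq_id: str
    orf0_start: int
    orf0_end: int
    orf1_end: int
    site: FrameshiftSite

    @property
    def cds_span(self) -> tuple[int, int]:
        """Half-open span of the full dual-ORF coding region."""
        return (self.orf0_start, self.orf1_end)


def scan_heptamers(
    sequence: str,
    orf_start: int = 0,
    motifs: dict[str, HeptamerMotif] | None = None,
    seq_id: str = "seq",
) -> list[FrameshiftSite]:
    """Find every heptamer occurrence in frame 0 relative to ``orf_start``.

    Occurrences whose start is out of phase with the anchor ORF are excluded;
    the returned sites are sorted by start position.
    """
    seq = normalize_sequence(sequence)
    if not 0 <= orf_start <= len(seq):
        raise HeptamerScanError(f"orf_start {orf_start} outside sequence of length {len(seq)}")
    table = _MOTIF_BY_DNA if motifs is None else {m.dna: m for m in motifs.values()}
    sites = []
    for dna, motif in table.items():
        pos = seq.find(dna)
        while pos != -1:
            if (pos - orf_start) % 3 == 0:
                sites.append(FrameshiftSite(seq_id, pos, motif, orf_start))
            pos = seq.find(dna, pos + 1)
    return sorted(sites, key=lambda s: s.start)


def build_dual_orf_model(sequence: str, site: FrameshiftSite) -> DualOrfGeneModel:
    """Close a frameshift site into a dual-ORF gene model.

    The 0-frame ORF ends at the first in-frame stop at or after the heptamer
    (for the OAZ1-type heptamer this is the TGA inside the heptamer itself);
    the +1-frame ORF ends at the first stop read from ``site.start + 4``.
    Raises :class:`OpenModelError` if either stop is missing before the end of
    the sequence.
    """
    seq = normalize_sequence(sequence)
    orf_start = site.orf_start
    if seq[orf_start : orf_start + 3] != START_CODON:
        raise HeptamerScanError(f"anchor ORF at {orf_start} does not start with ATG")
    if seq[site.start : site.start + 7] != site.motif.dna:
        raise HeptamerScanError(
            f"sequence at {site.start} does not spell the {site.motif.name} heptamer"
        )
    if site.frame != 0:
        raise HeptamerScanError("frameshift site is out of frame with its anchor ORF")
    for p in range(orf_start, site.start, 3):
        if seq[p : p + 3] in STOP_CODONS:
            raise HeptamerScanError(
                f"0-frame stop at {p} upstream of the heptamer: site not inside the ORF"
            )

    orf0_end = _first_stop_end(seq, site.start)
    if orf0_end is None:
        raise OpenModelError(f"{site.seq_id}: no 0-frame stop codon at/after the heptamer")
    orf1_end = _first_stop_end(seq, site.start + 4)
    if orf1_end is None:
        raise OpenModelError(f"{site.seq_id}: no +1-frame stop codon after the heptamer")
    return DualOrfGeneModel(site.seq_id, orf_start, orf0_end, orf1_end, site)


def _first_stop_end(seq: str, start: int) -> int | None:
    for p in range(start, len(seq) - 2, 3):
        if seq[p : p + 3] in STOP_CODONS:
            return p + 3
    return None


def fuse_frames(sequence: str, model: DualOrfGeneModel) -> str:
    """Join the two frames into one in-frame CDS by deleting heptamer base 4.

    Deleting the fourth heptamer nucleotide (e.g. CTTAGGC -> CTTGGC) places the
    +1 ORF in frame with the 0-frame portion up to the P-site codon, exactly as
    used to align frameshifted genes against non-frameshifting homologues.  The
    output is one nucleotide shorter than the dual-ORF CDS span.
    """
    seq = normalize_sequence(sequence)
    s = model.site.start
    return seq[model.orf0_start : s + 3] + seq[s + 4 : model.orf1_end]


def trans_frame_protein(sequence: str, model: DualOrfGeneModel) -> str:
    """Predict the trans-frame protein encoded across the frameshift.

    Equals the standard translation of :func:`fuse_frames` output up to (and
    excluding) its stop; equivalently the 0-frame peptide through the P-site
    codon followed by the +1-frame peptide.
    """
    fused = fuse_frames(sequence, model)
    protein = str(Seq(fused).translate())
    if not protein.endswith("*"):
        raise OpenModelError(f"{model.seq_id}: fused CDS does not end at a stop codon")
    body = protein[:-1]
    if "*" in body:
        raise HeptamerScanError(
            f"{model.seq_id}: internal stop in the fused frame at codon {body.index('*')}"
        )
    return body


# ---------------------------------------------------------------------------
# I/O: FASTA sequences, GFF3 anchors/models, TSV site tables
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read sequences into {id: normalised DNA string}."""
    return {rec.id: normalize_sequence(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def read_orf_anchors(path) -> list[tuple[str, int, int, str]]:
    """Read CDS features from GFF3 as (seq_id, start0, end, feature_id).

    Only ``CDS`` features are consumed; coordinates are converted from the
    GFF3 1-based closed convention to 0-based half-open.
    """
    anchors = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            anchors.append(
                (fields[0], int(fields[3]) - 1, int(fields[4]), attrs.get("ID", "cds"))
            )
    return anchors


def write_models_gff3(models: list[DualOrfGeneModel], path) -> None:
    """Write dual-ORF models as paired CDS features with a frameshift attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, m in enumerate(models):
            gene_id = f"fsgene{k + 1}"
            fh.write(
                "\t".join(
                    [m.seq_id, "riboshift", "gene", str(m.orf0_start + 1),
                     str(m.orf1_end), ".", "+", ".", f"ID={gene_id};frameshift=+1"]
                ) + "\n"
            )
            fh.write(
                "\t".join(
                    [m.seq_id, "riboshift", "CDS", str(m.orf0_start + 1),
                     str(m.orf0_end), ".", "+", "0",
                     f"ID={gene_id}.orf0;Parent={gene_id};frameshift=+1"]
                ) + "\n"
            )
            fh.write(
                "\t".join(
                    [m.seq_id, "riboshift", "CDS", str(m.site.start + 5),
                     str(m.orf1_end), ".", "+", "0",
                     f"ID={gene_id}.orf1;Parent={gene_id};frameshift=+1"]
                ) + "\n"
            )


def write_site_table(models: list[DualOrfGeneModel], path) -> None:
    """Write a TSV site report (heptamer start is 1-based in the report)."""
    with open(path, "w") as fh:
        fh.write("seq_id\theptamer_start\tmotif\theptamer\torf0_start\torf0_end\torf1_end\n")
        for m in models:
            fh.write(
                f"{m.seq_id}\t{m.site.start + 1}\t{m.site.motif.name}\t"
                f"{m.site.motif.dna}\t{m.orf0_start + 1}\t{m.orf0_end}\t{m.orf1_end}\n"
            )
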