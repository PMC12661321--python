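"""Synonymous-site conservation scanning over codon alignments.

Overlapping functional elements in a coding sequence — an RNA structure, a
second reading frame — constrain nucleotide positions that are free at the
protein level, so they show up as a local deficit of synonymous
substitutions.  This module builds codon alignments by back-translating a
protein alignment onto the source CDSs, classifies each codon against a
designated reference row as identical / synonymous / non-synonymous / gap,
and runs a sliding-window observed/expected synonymous-substitution scan
(default window 17 codons).

The neutral expectation is deliberately simple: the alignment-wide per-slot
synonymous rate, where a "slot" is a (row, column) pair whose amino acid
matches the reference (only codons that *could* be synonymous variants
count).  Each window is tested against a one-sided binomial lower tail.
This is a desk-scale stand-in for phylogeny-aware scans (Synplot2-style):
ratios and p-values are comparable in kind, not in value, to tools that
model the tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

GAP_CODON = "---"

#: codon -> amino acid (standard nuclear code), '*' for stops.
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TO_AA.update({c: "*" for c in standard_dna_table.stop_codons})

# substitution kinds
IDENTICAL, SYNONYMOUS, NON_SYNONYMOUS, GAP = "identical", "synonymous", "non_synonymous", "gap"


@dataclass(frozen=True)
class SubstitutionCall:
    row: int
    column: int
    kind: str


@dataclass
class WindowStat:
    """Observed vs expected synonymous substitutions in one window.

    ``p_value`` is the one-sided binomial lower tail P(X <= observed) with
    n = eligible slots in the window and p = the alignment-wide rate; windows
    with no eligible slots are flagged undefined.
    """

    center_codon: int
    observed_syn: int
    expected_syn: float
    ratio: float
    p_value: float
    n_slots: int
    defined: bool = True
    q_value: float | None = None


@dataclass
class CodonAlignment:
    """A gapped codon-resolution multiple alignment with a reference row.

    ``rows[r][c]`` is the 3-letter codon of sequence ``r`` at codon column
    ``c``, or ``---`` for a gap.
    """

    names: list[str]
    rows: list[list[str]]
    reference_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        ncol = len(self.rows[0])
        for name, row in zip(self.names, self.rows):
            if len(row) != ncol:
                raise ValueError(f"row {name!r} has {len(row)} codons, expected {ncol}")
            for c, codon in enumerate(row):
                if codon != GAP_CODON and (len(codon) != 3 or set(codon) - set("ACGT")):
                    raise ValueError(f"row {name!r} column {c}: invalid codon {codon!r}")
        if not 0 <= self.reference_index < len(self.rows):
            raise ValueError("reference_index out of range")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


def back_translate_alignment(
    names: list[str],
    protein_rows: list[str],
    cds_sequences: dict[str, str],
    reference_index: int = 0,
) -> CodonAlignment:
    """Thread each CDS through its gapped protein row, codon by codon.

    For every row, the translation of the ungapped CDS (standard code, any
    trailing stop stripped) must equal the ungapped protein row; each amino
    acid is then replaced by its source codon and each gap by ``---``.
    """
    rows = []
    for name, prot in zip(names, protein_rows):
        cds = cds_sequences[name].upper().replace("U", "T")
        if len(cds) % 3:
            raise ValueError(f"{name}: CDS length {len(cds)} is not a multiple of 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and CODON_TO_AA.get(codons[-1]) == "*":
            codons = codons[:-1]
        residues = [aa for aa in prot if aa != "-"]
        translated = "".join(CODON_TO_AA.get(c, "X") for c in codons)
        if translated != "".join(residues):
            mismatch = next(
                (i for i, (a, b) in enumerate(zip(translated, residues)) if a != b),
                min(len(translated), len(residues)),
            )
            raise ValueError(
                f"{name}: CDS translation does not match protein row "
                f"(first mismatch at residue {mismatch})"
            )
        it = iter(codons)
        rows.append([GAP_CODON if aa == "-" else next(it) for aa in prot])
    return CodonAlignment(list(names), rows, reference_index)


def classify_columns(aln: CodonAlignment) -> list[SubstitutionCall]:
    """Classify every non-reference codon against the reference row."""
    calls = []
    ref = aln.rows[aln.reference_index]
    for r, row in enumerate(aln.rows):
        if r == aln.reference_index:
            continue
        for c, codon in enumerate(row):
            calls.append(SubstitutionCall(r, c, classify_codon_pair(ref[c], codon)))
    return calls


def classify_codon_pair(ref_codon: str, codon: str) -> str:
    """identical / synonymous / non_synonymous / gap for one codon pair."""
    if GAP_CODON in (ref_codon, codon):
        return GAP
    if codon == ref_codon:
        return IDENTICAL
    if CODON_TO_AA[codon] == CODON_TO_AA[ref_codon]:
        return SYNONYMOUS
    return NON_SYNONYMOUS


def _call_matrices(aln: CodonAlignment) -> tuple[np.ndarray, np.ndarray]:
    """(eligible, synonymous) boolean matrices over non-reference rows.

    A slot is eligible when neither codon is a gap and both encode the same
    amino acid — i.e. the codon could be a synonymous variant of the
    reference.  ``synonymous`` marks eligible slots whose codons differ.
    """
    ref = aln.rows[aln.reference_index]
    ref_aa = np.array([CODON_TO_AA.get(c, "-") for c in ref])
    ref_arr = np.array(ref)
    eligible_rows, syn_rows = [], []
    for r, row in enumerate(aln.rows):
        if r == aln.reference_index:
            continue
        arr = np.array(row)
        aa = np.array([CODON_TO_AA.get(c, "-") for c in row])
        nongap = (arr != GAP_CODON) & (ref_arr != GAP_CODON)
        eligible = nongap & (aa == ref_aa)
        eligible_rows.append(eligible)
        syn_rows.append(eligible & (arr != ref_arr))
    return np.array(eligible_rows), np.array(syn_rows)


def window_synonymy_scan(
    aln: CodonAlignment, window: int = 17, bh_correct: bool = False
) -> list[WindowStat]:
    """Sliding-window observed/expected synonymous-substitution scan.

    Step is one codon; only full windows are scored (truncated edge windows
    are skipped).  ``bh_correct=True`` adds Benjamini–Hochberg q-values over
    the defined windows; raw p-values are reported either way.
    """
    ncol = aln.n_columns
    if window < 3:
        raise ValueError("window must be at least 3 codons")
    if window > ncol:
        raise ValueError(f"window {window} exceeds alignment length {ncol}")
    eligible, syn = _call_matrices(aln)
    slots_per_col = eligible.sum(axis=0)
    syn_per_col = syn.sum(axis=0)
    total_slots = int(slots_per_col.sum())
    total_syn = int(syn_per_col.sum())
    p_global = total_syn / total_slots if total_slots else 0.0

    kernel = np.ones(window, dtype=int)
    win_slots = np.convolve(slots_per_col, kernel, mode="valid")
    win_syn = np.convolve(syn_per_col, kernel, mode="valid")
    centers = np.arange(ncol - window + 1) + window // 2

    out = []
    for center, n, obs in zip(centers, win_slots, win_syn):
        n, obs = int(n), int(obs)
        expected = p_global * n
        if n == 0 or p_global == 0.0:
            out.append(
                WindowStat(int(center), obs, expected, math.nan, math.nan, n, defined=False)
            )
            continue
        ratio = obs / expected
        p_value = float(stats.binom.cdf(obs, n, p_global))
        out.append(WindowStat(int(center), obs, expected, ratio, p_value, n))
    if bh_correct:
        defined = [w for w in out if w.defined]
        if defined:
            qs = stats.false_discovery_control([w.p_value for w in defined])
            for w, q in zip(defined, qs):
                w.q_value = float(q)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_codon_alignment_fasta(path, reference_id: str | None = None) -> CodonAlignment:
    """Read a pre-built codon alignment from aligned FASTA (gap '-', in-frame)."""
    from Bio import SeqIO

    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper().replace("U", "T")
        if len(s) % 3:
            raise ValueError(f"{rec.id}: aligned length {len(s)} is not a multiple of 3")
        names.append(rec.id)
        rows.append([s[i : i + 3] for i in range(0, len(s), 3)])
    ref = 0 if reference_id is None else names.index(reference_id)
    return CodonAlignment(names, rows, ref)


def write_codon_alignment_fasta(aln: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.names, aln.rows):
            fh.write(f">{name}\n{''.join(row)}\n")


def write_window_stats_tsv(stats_list: list[WindowStat], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "center_codon": w.center_codon,
                "observed_syn": w.observed_syn,
                "expected_syn": w.expected_syn,
                "ratio": w.ratio,
                "p_value": w.p_value,
                "q_value": w.q_value,
                "n_slots": w.n_slots,
                "defined": w.defined,
            }
            for w in stats_list
        ]
    ).to_csv(path, sep="\t", index=False)


def write_substitution_calls_tsv(aln: CodonAlignment, path) -> None:
    """Per-codon substitution classes (the alignment-colouring track)."""
    import pandas as pd

    calls = classify_columns(aln)
    pd.DataFrame(
        [
            {"row": aln.names[c.row], "column": c.column, "kind": c.kind}
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)
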