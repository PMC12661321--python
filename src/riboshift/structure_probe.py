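"""Upstream stem-loop detection and chemical-probing consistency.

A hairpin immediately 5' of a +1 frameshift site can stimulate frameshifting:
as the emerging mRNA folds it pulls the message backwards through the
ribosome, favouring forward slippage of the P-site tRNA.  The analysis needs
two things from a folding step: *is there a stable hairpin in this window*
and *where does its base sit relative to the heptamer*.  Both are answered
here with a lightweight single-hairpin dynamic programme over stacking
scores.  The scores are ordinal, not free energies: a Watson-Crick pair in a
stack contributes +2, a G.U wobble +1, each bulge/internal loop -2 and
opening the hairpin -3, with at most two internal loops/bulges of at most
3 nt each and a terminal loop of at least 3 nt.  Full nearest-neighbour
thermodynamics is deliberately out of scope.

DMS chemistry methylates *unpaired* adenosines and cytosines, so a real
hairpin shows depressed reactivity over its paired A/C bases.  Agreement
between a proposed hairpin and a reactivity track is scored as a rank
statistic (the probability that a random unpaired A/C out-reacts a random
paired A/C), which is invariant to the scale of the reactivity units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .heptamer_scan import FrameshiftSite, normalize_sequence

logger = logging.getLogger(__name__)

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "T"), ("T", "G")}

STACK_WC = 2
STACK_GU = 1
LOOP_PENALTY = -2
OPEN_PENALTY = -3
MAX_LOOP_NT = 3       # max unpaired nt in one bulge/internal loop
MAX_LOOPS = 2         # max bulges/internal loops per helix
MIN_HAIRPIN_LOOP = 3  # min terminal loop length
MAX_WINDOW = 200


@dataclass
class StemLoop:
    """A single hairpin: nested pairs, terminal loop, stability score.

    ``pairs`` are (i, j) 0-based paired positions, outermost first; ``loop``
    and ``span`` are half-open intervals; ``score`` is in stacking-score
    units (higher = more stable); ``spacer_nt`` is filled in by
    :func:`spacer_to_site` when a frameshift site is attached.
    """

    pairs: list[tuple[int, int]]
    loop: tuple[int, int]
    span: tuple[int, int]
    score: int
    spacer_nt: int | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class ReactivityTrack:
    """Per-position chemical reactivities over a transcript.

    Meaningful only at A/C bases (DMS chemistry); NaN marks unprobed or
    non-A/C positions and is ignored in scoring.
    """

    bases: str
    reactivity: np.ndarray

    def __post_init__(self) -> None:
        self.reactivity = np.asarray(self.reactivity, dtype=float)
        if len(self.reactivity) != len(self.bases):
            raise ValueError("reactivity vector and base string lengths differ")
        with np.errstate(invalid="ignore"):
            if np.any(self.reactivity < 0):
                raise ValueError("reactivities must be non-negative")


def _pair_score(x: str, y: str) -> int | None:
    if (x, y) in WC_PAIRS:
        return STACK_WC
    if (x, y) in GU_PAIRS:
        return STACK_GU
    return None


def find_best_hairpin(
    sequence: str, search_window: tuple[int, int] | None = None
) -> StemLoop | None:
    """Maximum-score single hairpin in a window, or None if nothing stable.

    Dynamic programme over states (outer pair i..j, internal loops used).
    Ties are broken towards the longer helix, then the 5'-most hairpin.
    Windows above 200 nt are refused — scan in tiles instead.
    """
    seq = normalize_sequence(sequence)
    lo, hi = search_window if search_window is not None else (0, len(seq))
    if not 0 <= lo <= hi <= len(seq):
        raise ValueError(f"window {search_window} outside sequence")
    if hi - lo > MAX_WINDOW:
        raise ValueError(f"window longer than {MAX_WINDOW} nt: fold in tiles instead")
    sub = seq[lo:hi]
    n = len(sub)

    # memo[(i, j, loops)] = (helix score from pair (i,j) inward, n_pairs, choice)
    # choice is None for the innermost pair, else the (a, b) gap widths.
    memo: dict[tuple[int, int, int], tuple[int, int, tuple[int, int] | None] | None] = {}

    def helix(i: int, j: int, loops: int):
        ps = _pair_score(sub[i], sub[j])
        if ps is None:
            return None
        key = (i, j, loops)
        if key in memo:
            return memo[key]
        best = (ps, 1, None) if j - i - 1 >= MIN_HAIRPIN_LOOP else None
        for a in range(MAX_LOOP_NT + 1):
            for b in range(MAX_LOOP_NT + 1 - a):
                gap = (a, b) != (0, 0)
                nl = loops + gap
                if nl > MAX_LOOPS:
                    continue
                i2, j2 = i + 1 + a, j - 1 - b
                if i2 >= j2:
                    continue
                inner = helix(i2, j2, nl)
                if inner is None:
                    continue
                cand = (ps + (LOOP_PENALTY if gap else 0) + inner[0], 1 + inner[1], (a, b))
                if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                    best = cand
        memo[key] = best
        return best

    top: tuple[int, int, int, int] | None = None  # (score, n_pairs, i, j)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            r = helix(i, j, 0)
            if r is None:
                continue
            score = r[0] + OPEN_PENALTY
            if top is None or (score, r[1]) > (top[0], top[1]):
                top = (score, r[1], i, j)
    if top is None or top[0] <= 0:
        return None

    score, _, i, j = top
    pairs = [(i, j)]
    loops = 0
    while True:
        entry = memo[(i, j, loops)]
        assert entry is not None
        choice = entry[2]
        if choice is None:
            break
        a, b = choice
        loops += a + b > 0
        i, j = i + 1 + a, j - 1 - b
        pairs.append((i, j))
    loop = (pairs[-1][0] + 1, pairs[-1][1])
    span = (pairs[0][0] + lo, pairs[0][1] + 1 + lo)
    pairs = [(x + lo, y + lo) for x, y in pairs]
    return StemLoop(pairs, (loop[0] + lo, loop[1] + lo), span, score)


def enumerate_hairpins(sequence: str) -> list[tuple[int, list[tuple[int, int]]]]:
    """Exhaustively enumerate every legal single hairpin with its score.

    Reference enumeration for validating the dynamic programme; practical
    only for short windows (<= ~15 nt).  Returns (score, pairs) tuples.
    """
    seq = normalize_sequence(sequence)
    n = len(seq)
    out: list[tuple[int, list[tuple[int, int]]]] = []

    def extend(i: int, j: int, loops: int, score: int, pairs: list[tuple[int, int]]):
        if j - i - 1 >= MIN_HAIRPIN_LOOP:
            out.append((score + OPEN_PENALTY, list(pairs)))
        for a in range(MAX_LOOP_NT + 1):
            for b in range(MAX_LOOP_NT + 1 - a):
                gap = (a, b) != (0, 0)
                if loops + gap > MAX_LOOPS:
                    continue
                i2, j2 = i + 1 + a, j - 1 - b
                if i2 >= j2:
                    continue
                ps = _pair_score(seq[i2], seq[j2])
                if ps is None:
                    continue
                pairs.append((i2, j2))
                extend(i2, j2, loops + gap,
                       score + ps + (LOOP_PENALTY if gap else 0), pairs)
                pairs.pop()

    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            ps = _pair_score(seq[i], seq[j])
            if ps is not None:
                extend(i, j, 0, ps, [(i, j)])
    return out


def spacer_to_site(stem: StemLoop, site: FrameshiftSite) -> tuple[int, int | None]:
    """Distance from the hairpin base to the heptamer, in nt and whole codons.

    Returns (spacer_nt, spacer_codons); codons is None when the nt distance
    is not a multiple of three.
    """
    spacer_nt = site.start - stem.span[1]
    if spacer_nt < 0:
        raise ValueError("stem-loop is not upstream of the frameshift site")
    stem.spacer_nt = spacer_nt
    return spacer_nt, spacer_nt // 3 if spacer_nt % 3 == 0 else None


def dms_consistency(stem: StemLoop, track: ReactivityTrack) -> float:
    """Rank-based agreement between a hairpin and DMS reactivities, in [0, 1].

    The probability that a randomly chosen unpaired A/C within the hairpin
    span out-reacts a randomly chosen paired A/C (ties count 1/2): 1.0 is
    perfect support for the structure, 0.5 is no signal.  Returns NaN with a
    warning if either class has no eligible base.
    """
    lo, hi = stem.span
    if hi > len(track.bases):
        raise ValueError("reactivity track does not cover the stem span")
    paired_pos = {p for ij in stem.pairs for p in ij}
    paired_vals, unpaired_vals = [], []
    for p in range(lo, hi):
        if track.bases[p] not in "AC" or math.isnan(track.reactivity[p]):
            continue
        (paired_vals if p in paired_pos else unpaired_vals).append(track.reactivity[p])
    if not paired_vals or not unpaired_vals:
        logger.warning("dms_consistency: no eligible paired/unpaired A/C bases; undefined")
        return math.nan
    u, _ = stats.mannwhitneyu(unpaired_vals, paired_vals, alternative="two-sided")
    return float(u) / (len(paired_vals) * len(unpaired_vals))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def to_dot_bracket(stem: StemLoop, length: int | None = None, offset: int = 0) -> str:
    """Dot-bracket string for the hairpin, over ``length`` positions."""
    n = length if length is not None else stem.span[1] - offset
    chars = ["."] * n
    for i, j in stem.pairs:
        chars[i - offset] = "("
        chars[j - offset] = ")"
    return "".join(chars)


def write_structure(path, seq_id: str, sequence: str, stem: StemLoop) -> None:
    """FASTA-like 2-line record plus a dot-bracket structure line."""
    lo, hi = stem.span
    with open(path, "w") as fh:
        fh.write(f">{seq_id} span={lo}-{hi} score={stem.score}\n")
        fh.write(sequence[lo:hi] + "\n")
        fh.write(to_dot_bracket(stem, length=hi - lo, offset=lo) + "\n")


def read_reactivity_tsv(path, length: int | None = None) -> ReactivityTrack:
    """Read reactivities from TSV: pos (1-based), base, reactivity."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["pos", "base", "reactivity"])
    n = length if length is not None else int(df["pos"].max())
    bases = ["N"] * n
    vals = np.full(n, np.nan)
    for pos, base, val in df.itertuples(index=False):
        bases[int(pos) - 1] = str(base).upper().replace("U", "T")
        vals[int(pos) - 1] = float(val)
    return ReactivityTrack("".join(bases), vals)


def write_reactivity_tsv(track: ReactivityTrack, path) -> None:
    with open(path, "w") as fh:
        for p, (base, val) in enumerate(zip(track.bases, track.reactivity), start=1):
            if not math.isnan(val):
                fh.write(f"{p}\t{base}\t{val:.6g}\n")
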