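"""Ground-truth simulators for every input the pipeline consumes.

Each generator emulates one of the data classes the analyses run on —
frameshift genes, frame-resolved footprint profiles, codon alignments with a
locally constrained synonymous rate, dual-luciferase replicate readings, and
DMS reactivity tracks — with the true parameters recorded, so every stage of
the pipeline can be exercised and calibrated without external downloads.

All generators are bit-reproducible for a fixed seed.  Frameshifting is
modelled as a branch at the heptamer: a traversing ribosome continues into
the +1 frame with probability ``theta`` and otherwise terminates at the
0-frame stop.  Elongation is uniform apart from gamma-distributed per-codon
rate multipliers; no attempt is made to model tRNA kinetics, library-prep
biases, UTRs or reinitiation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .conservation_scan import CODON_TO_AA, CodonAlignment
from .heptamer_scan import (
    MOTIFS,
    STOP_CODONS,
    DualOrfGeneModel,
    FrameshiftSite,
    build_dual_orf_model,
)
from .reporter_quant import LuciferaseReplicate
from .ribo_quant import RiboProfile
from .structure_probe import ReactivityTrack, StemLoop

SENSE_CODONS = sorted(set(CODON_TO_AA) - {c for c, a in CODON_TO_AA.items() if a == "*"})
_STOPS = sorted(STOP_CODONS)

#: synonymous alternatives per sense codon (may be empty: ATG, TGG)
SYNONYMOUS_ALTERNATIVES: dict[str, list[str]] = {
    c: sorted(o for o in SENSE_CODONS if o != c and CODON_TO_AA[o] == CODON_TO_AA[c])
    for c in SENSE_CODONS
}

#: single-nucleotide neighbours encoding a different amino acid (stops excluded)
_NT = "ACGT"
NONSYN_NEIGHBOURS: dict[str, list[str]] = {
    c: sorted(
        c[:i] + n + c[i + 1 :]
        for i in range(3)
        for n in _NT
        if n != c[i]
        and CODON_TO_AA.get(c[:i] + n + c[i + 1 :]) not in ("*", None, CODON_TO_AA[c])
    )
    for c in SENSE_CODONS
}


@dataclass
class SimConfig:
    """Study conditions for the simulators.

    theta
        True frameshifting efficiency (fraction of ribosomes taking the +1
        branch at the heptamer).
    depth
        Expected total footprint count over the gene.
    frame_fidelity
        Probability that a footprint's P-site lands on its ribosome's true
        frame; the remainder spills +/-1 nt.
    per_codon_dispersion
        Gamma shape for codon-level rate multipliers (mean 1); 0 disables
        dispersion.
    syn_rate / nonsyn_rate
        Per-(row, codon) substitution probabilities for alignment evolution.
    constraint_factor
        Multiplier on ``syn_rate`` inside the designated constrained window.
    luc_sigma
        Lognormal sd of replicate noise in the luciferase simulator.
    dms_snr
        Mean unpaired/paired reactivity ratio in the DMS simulator.
    """

    seed: int = 0
    theta: float = 0.4
    depth: float = 100_000
    frame_fidelity: float = 0.9
    per_codon_dispersion: float = 5.0
    syn_rate: float = 0.1
    nonsyn_rate: float = 0.03
    constraint_factor: float = 1.0
    luc_sigma: float = 0.1
    dms_snr: float = 2.0
    motif: str = "Ty1-type"
    orf0_codons: int = 50
    orf1_codons: int = 30
    stop0_offset_codons: int = 2
    n_replicates: int = 8
    n_rows: int = 20

    def __post_init__(self) -> None:
        for name in ("theta", "frame_fidelity", "syn_rate", "nonsyn_rate", "constraint_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}; known: {sorted(MOTIFS)}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Gene construction
# ---------------------------------------------------------------------------

def simulate_gene(
    config: SimConfig, rng: np.random.Generator | None = None, seq_id: str = "simgene"
) -> tuple[str, DualOrfGeneModel]:
    """Construct a random CDS carrying exactly one in-frame frameshift heptamer.

    The 0-frame ORF spans ``orf0_codons`` codons (ATG through stop) with the
    heptamer placed so that the 0-frame stop falls ``stop0_offset_codons``
    codons after the 0-frame A-site codon (for the OAZ1-type heptamer the
    stop is the TGA inside the heptamer itself); the +1 ORF spans
    ``orf1_codons`` sense codons plus its stop.  Candidates containing any
    accidental heptamer occurrence, at any offset, are rejection-sampled.
    """
    rng = config.rng() if rng is None else rng
    motif = MOTIFS[config.motif]
    g = 0 if motif.name == "OAZ1-type" else config.stop0_offset_codons
    if motif.name != "OAZ1-type":
        if g < 1:
            raise ValueError("stop0_offset_codons must be >= 1 for non-OAZ1 motifs")
        if g == 1 and motif.a1_codon[2] != "T":
            raise ValueError(f"{motif.name}: a 0-frame stop cannot directly follow the A-site")
    u = config.orf0_codons - 3 - g
    m = config.orf1_codons
    if u < 0:
        raise ValueError("orf0_codons too small for this motif/stop offset")
    if m < g + 1:
        raise ValueError("orf1_codons must exceed the 0-frame overlap")

    s = 3 * (u + 1)  # heptamer start
    for _ in range(10_000):
        upstream = [SENSE_CODONS[k] for k in rng.integers(len(SENSE_CODONS), size=u)]
        plus1 = [motif.a1_codon] + [
            SENSE_CODONS[k] for k in rng.integers(len(SENSE_CODONS), size=m - 1)
        ]
        stop1 = _STOPS[rng.integers(3)]
        if g >= 1:
            # plant the 0-frame stop g codons past the A0 codon; its bases
            # overlap +1 codons g-1 and g without ever creating a +1 stop
            stop0 = _STOPS[rng.integers(3)]
            plus1[g - 1] = plus1[g - 1][:2] + stop0[0]
            plus1[g] = stop0[1:3] + plus1[g][2]
        seq = "ATG" + "".join(upstream) + motif.dna + "".join(plus1[1:]) + stop1

        # no premature 0-frame stop between the A0 codon and the planted stop
        if any(seq[p : p + 3] in STOP_CODONS for p in range(s + 6, s + 3 + 3 * g, 3)):
            continue
        # exactly the planted heptamer occurrence, at any offset, any motif
        hits = [
            (p, dna)
            for dna in (mm.dna for mm in MOTIFS.values())
            for p in range(len(seq) - 6)
            if seq[p : p + 7] == dna
        ]
        if hits != [(s, motif.dna)]:
            continue

        site = FrameshiftSite(seq_id, s, motif, orf_start=0)
        model = build_dual_orf_model(seq, site)
        assert model.orf0_end == s + 6 + 3 * g
        assert model.orf1_end == len(seq)
        return seq, model
    raise RuntimeError("gene rejection sampling failed to converge")


# ---------------------------------------------------------------------------
# Ribosome profiling
# ---------------------------------------------------------------------------

def simulate_ribo_profile(
    sequence: str,
    model: DualOrfGeneModel,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> RiboProfile:
    """Frame-resolved P-site footprint counts over a dual-ORF gene.

    Every ribosome traverses the 0-frame ORF to the heptamer; a fraction
    ``theta`` branches into the +1 ORF, the rest runs to the 0-frame stop.
    Per-codon counts are Poisson with gamma-distributed rate multipliers,
    normalised so the expected total is ``depth``; each footprint lands on
    its codon's first nucleotide with probability ``frame_fidelity`` and
    spills one nucleotide left or right otherwise.
    """
    rng = config.rng() if rng is None else rng
    s = model.site.start
    pre = np.arange(model.orf0_start, s + 1, 3)
    post0 = np.arange(s + 3, model.orf0_end, 3)
    plus1 = np.arange(s + 4, model.orf1_end, 3)
    starts = np.concatenate([pre, post0, plus1])
    flux = np.concatenate(
        [
            np.ones(len(pre)),
            np.full(len(post0), 1.0 - config.theta),
            np.full(len(plus1), config.theta),
        ]
    )
    if config.per_codon_dispersion > 0:
        k = config.per_codon_dispersion
        rates = rng.gamma(k, 1.0 / k, size=len(starts))
    else:
        rates = np.ones(len(starts))
    weights = flux * rates
    lam = config.depth * weights / weights.sum()
    per_codon = rng.poisson(lam)

    stay = rng.binomial(per_codon, config.frame_fidelity)
    spill = per_codon - stay
    left = rng.binomial(spill, 0.5)
    right = spill - left

    counts = np.zeros(len(sequence), dtype=np.int64)
    np.add.at(counts, starts, stay)
    for shift, amount in ((-1, left), (1, right)):
        pos = starts + shift
        ok = (pos >= 0) & (pos < len(sequence))
        np.add.at(counts, pos[ok], amount[ok])
    return RiboProfile(model.seq_id, counts)


# ---------------------------------------------------------------------------
# Codon alignment evolution
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    reference_cds: str,
    n_rows: int,
    config: SimConfig,
    constraint_window: tuple[int, int] | None = None,
    freeze_columns: set[int] | frozenset[int] = frozenset(),
    rng: np.random.Generator | None = None,
) -> CodonAlignment:
    """Evolve orthologous rows from a reference CDS, codon by codon.

    Each non-reference codon mutates to a random synonymous alternative with
    probability ``syn_rate`` (times ``constraint_factor`` inside the
    half-open codon window ``constraint_window``) and to a non-synonymous
    single-nucleotide neighbour with independent probability ``nonsyn_rate``.
    Columns in ``freeze_columns`` (e.g. the heptamer codons, universally
    conserved in the genus) and stop-codon columns are copied verbatim.
    No indels are introduced, so the alignment is gapless.
    """
    rng = config.rng() if rng is None else rng
    cds = reference_cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError("reference CDS length must be a multiple of 3")
    ref = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    ncod = len(ref)
    p_syn = np.full(ncod, config.syn_rate)
    if constraint_window is not None:
        lo, hi = constraint_window
        p_syn[lo:hi] *= config.constraint_factor

    names = ["ref"] + [f"ortholog{r:02d}" for r in range(1, n_rows)]
    rows = [list(ref)]
    for _ in range(1, n_rows):
        draws = rng.random(ncod)
        row = []
        for c, codon in enumerate(ref):
            if c in freeze_columns or CODON_TO_AA.get(codon) == "*":
                row.append(codon)
                continue
            if draws[c] < p_syn[c]:
                alts = SYNONYMOUS_ALTERNATIVES[codon]
                row.append(alts[rng.integers(len(alts))] if alts else codon)
            elif draws[c] < p_syn[c] + config.nonsyn_rate:
                alts = NONSYN_NEIGHBOURS[codon]
                row.append(alts[rng.integers(len(alts))] if alts else codon)
            else:
                row.append(codon)
        rows.append(row)
    return CodonAlignment(names, rows, reference_index=0)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random in-frame CDS: ATG, sense codons, one stop."""
    body = [SENSE_CODONS[k] for k in rng.integers(len(SENSE_CODONS), size=n_codons - 2)]
    return "ATG" + "".join(body) + _STOPS[rng.integers(3)]


# ---------------------------------------------------------------------------
# Dual-luciferase replicates
# ---------------------------------------------------------------------------

def simulate_luciferase(
    theta: float,
    config: SimConfig,
    n_replicates: int | None = None,
    rng: np.random.Generator | None = None,
    base_ratio: float = 0.5,
    renilla_level: float = 1.0e5,
) -> tuple[list[LuciferaseReplicate], list[LuciferaseReplicate]]:
    """Paired test and in-frame-control replicate readings.

    Control firefly/Renilla ratios are lognormal around ``base_ratio`` and
    test ratios around ``base_ratio * theta``; the multiplicative noise
    exp(sigma*Z - sigma^2/2) has unit mean, so the class-mean ratio of ratios
    is an unbiased estimate of theta.  Returns (tests, controls).
    """
    rng = config.rng() if rng is None else rng
    n = config.n_replicates if n_replicates is None else n_replicates
    sigma = config.luc_sigma

    def wells(cls: str, ratio: float) -> list[LuciferaseReplicate]:
        out = []
        for i in range(n):
            renilla = renilla_level * math.exp(rng.normal(0.0, 0.25))
            noise = math.exp(sigma * rng.normal() - 0.5 * sigma**2) if sigma > 0 else 1.0
            out.append(
                LuciferaseReplicate(f"{cls}_{i + 1}", cls, renilla * ratio * noise, renilla)
            )
        return out

    tests = wells("test", base_ratio * theta)
    controls = wells("in_frame_control", base_ratio)
    return tests, controls


# ---------------------------------------------------------------------------
# DMS reactivities
# ---------------------------------------------------------------------------

def simulate_dms(
    stem: StemLoop,
    sequence: str,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> ReactivityTrack:
    """Reactivity track consistent with a hairpin, over the full sequence.

    Within the stem span, unpaired A/C reactivities are exponential with
    mean ``dms_snr`` and paired A/C exponential with mean 1; G/T positions
    (and everything outside the span) are NaN, matching DMS chemistry.
    """
    rng = config.rng() if rng is None else rng
    seq = sequence.upper().replace("U", "T")
    vals = np.full(len(seq), np.nan)
    paired = {p for ij in stem.pairs for p in ij}
    for p in range(*stem.span):
        if seq[p] in "AC":
            mean = 1.0 if p in paired else config.dms_snr
            vals[p] = rng.exponential(mean)
    return ReactivityTrack(seq, vals)


# ---------------------------------------------------------------------------
# File bundle
# ---------------------------------------------------------------------------

def write_bundle(outdir, config: SimConfig, seq_id: str = "simgene") -> dict:
    """Generate one complete synthetic dataset on disk, plus a manifest.

    Emits FASTA, GFF3, per-nt footprint counts (TSV), luciferase replicates
    (TSV) and a DMS reactivity track (TSV) for a single simulated frameshift
    gene, along with ``manifest.json`` recording the seed and every true
    parameter.  All randomness derives from ``config.seed``.
    """
    from .heptamer_scan import write_models_gff3
    from .structure_probe import find_best_hairpin, write_reactivity_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()

    seq, model = simulate_gene(config, rng, seq_id=seq_id)
    profile = simulate_ribo_profile(seq, model, config, rng)
    tests, controls = simulate_luciferase(config.theta, config, rng=rng)

    with open(outdir / "gene.fasta", "w") as fh:
        fh.write(f">{seq_id}\n{seq}\n")
    write_models_gff3([model], outdir / "gene.gff3")
    with open(outdir / "counts.tsv", "w") as fh:
        for pos, c in enumerate(profile.counts, start=1):
            if c:
                fh.write(f"{seq_id}\t{pos}\t{c}\n")
    with open(outdir / "luciferase.tsv", "w") as fh:
        fh.write("sample_id\tconstruct_class\tfirefly\trenilla\n")
        for rep in tests + controls:
            fh.write(f"{rep.sample_id}\t{rep.construct_class}\t"
                     f"{rep.firefly:.6g}\t{rep.renilla:.6g}\n")

    upstream = (max(0, model.site.start - 60), model.site.start)
    stem = find_best_hairpin(seq, upstream)
    if stem is not None:
        track = simulate_dms(stem, seq, config, rng)
        write_reactivity_tsv(track, outdir / "dms.tsv")

    manifest = {
        "seq_id": seq_id,
        "config": asdict(config),
        "orf0_start": model.orf0_start,
        "orf0_end": model.orf0_end,
        "orf1_end": model.orf1_end,
        "heptamer_start": model.site.start,
        "has_dms": stem is not None,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
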