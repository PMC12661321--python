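"""Orchestration: scan -> quantify -> conserve -> fold as one configured run.

Stages communicate through plain files in the output directory so each one
can be inspected and re-run on its own.  A stage failure halts its
dependents but not independent stages; the run reports a combined
machine-readable summary (``summary.json``) covering, per frameshift site,
the ribosome-profiling efficiency, the reporter efficiency (when luciferase
data are supplied), the minimum-p conservation window, and the upstream
hairpin with its spacer and DMS support.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import (
    conservation_scan as cons,
    heptamer_scan as hs,
    reporter_quant as rq,
    ribo_quant as ribo,
    structure_probe as sp,
)

logger = logging.getLogger(__name__)

STAGES = ("scan", "ribofs", "lucfs", "consscan", "fold")
DEPENDS: dict[str, tuple[str, ...]] = {"ribofs": ("scan",), "fold": ("scan",)}

#: nt of sequence upstream of the heptamer searched for a stimulatory hairpin
FOLD_WINDOW_NT = 60


class ConfigError(ValueError):
    """The run configuration failed schema validation."""


@dataclass
class RunConfig:
    """Validated inputs and knobs for one pipeline run."""

    outdir: str
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    fasta: str | None = None
    gff3: str | None = None
    counts: str | None = None
    luciferase: str | None = None
    alignment: str | None = None
    reactivity: str | None = None
    motifs: list[str] | None = None
    trim_codons: int = 1
    mode: str = "region"
    region0_end: str = "psite"
    window: int = 17
    method: str = "mean_of_ratios"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        problems = []
        for stage in self.stages:
            if stage not in STAGES:
                problems.append(f"unknown stage {stage!r}")
        for name, need_stages in (
            ("fasta", {"scan", "ribofs", "fold"}),
            ("counts", {"ribofs"}),
            ("luciferase", {"lucfs"}),
            ("alignment", {"consscan"}),
        ):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                problems.append(f"{name} path does not exist: {path}")
            if path is None and need_stages & set(self.stages):
                missing = sorted(need_stages & set(self.stages))
                problems.append(f"{name} input required by stage(s) {missing}")
        if self.reactivity is not None and not Path(self.reactivity).exists():
            problems.append(f"reactivity path does not exist: {self.reactivity}")
        if self.motifs:
            for m in self.motifs:
                if m not in hs.MOTIFS:
                    problems.append(f"unknown motif {m!r}")
        if self.mode not in ("region", "frame"):
            problems.append(f"mode must be region|frame, got {self.mode!r}")
        if self.method not in ("mean_of_ratios", "ratio_of_means"):
            problems.append(f"unknown reporter method {self.method!r}")
        if self.trim_codons < 0:
            problems.append("trim_codons must be >= 0")
        if self.window < 3:
            problems.append("window must be >= 3 codons")
        if problems:
            raise ConfigError("; ".join(problems))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the summary.

    The summary (also written to ``<outdir>/summary.json``) records each
    stage's status and the combined per-site report.  Stages whose
    dependencies failed are skipped; the caller decides the exit status from
    ``summary["ok"]``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    status: dict[str, str] = {}
    ctx: dict = {"sites": []}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        deps = DEPENDS.get(stage, ())
        unmet = [d for d in deps if d in config.stages and status.get(d) != "ok"]
        if not unmet and any(d not in config.stages for d in deps):
            # dependency stage not requested: resume from its intermediates
            try:
                _load_models_from_sites(config, outdir, ctx)
            except Exception:
                logger.exception("stage %s: cannot resume from %s/sites.tsv", stage, outdir)
                unmet = [d for d in deps if d not in config.stages]
        if unmet:
            logger.error("stage %s skipped: unmet dependencies %s", stage, unmet)
            status[stage] = "skipped"
            continue
        try:
            _STAGE_FUNCS[stage](config, outdir, ctx)
            status[stage] = "ok"
        except Exception:
            logger.exception("stage %s failed", stage)
            status[stage] = "failed"

    summary = {
        "ok": all(v == "ok" for v in status.values()),
        "stages": status,
        "sites": ctx["sites"],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _load_models_from_sites(config: RunConfig, outdir: Path, ctx: dict) -> None:
    """Rebuild gene models from a previous run's sites.tsv (stage resume)."""
    if ctx.get("models"):
        return
    import pandas as pd

    seqs = hs.read_fasta(config.fasta)
    df = pd.read_csv(outdir / "sites.tsv", sep="\t")
    models = []
    for row in df.itertuples(index=False):
        site = hs.FrameshiftSite(
            str(row.seq_id), int(row.heptamer_start) - 1,
            hs.MOTIFS[str(row.motif)], int(row.orf0_start) - 1,
        )
        models.append(hs.build_dual_orf_model(seqs[site.seq_id], site))
    ctx["seqs"] = seqs
    ctx["models"] = models
    ctx["sites"] = [
        {
            "seq_id": m.seq_id,
            "heptamer_start": m.site.start,
            "motif": m.site.motif.name,
            "orf0_start": m.orf0_start,
            "orf0_end": m.orf0_end,
            "orf1_end": m.orf1_end,
        }
        for m in models
    ]


def _selected_motifs(config: RunConfig) -> dict[str, hs.HeptamerMotif]:
    if not config.motifs:
        return hs.MOTIFS
    return {name: hs.MOTIFS[name] for name in config.motifs}


def _stage_scan(config: RunConfig, outdir: Path, ctx: dict) -> None:
    seqs = hs.read_fasta(config.fasta)
    anchors = (
        hs.read_orf_anchors(config.gff3)
        if config.gff3
        else [(sid, 0, len(s), sid) for sid, s in seqs.items()]
    )
    models = []
    for seq_id, start, _end, _fid in anchors:
        seq = seqs[seq_id]
        for site in hs.scan_heptamers(seq, start, _selected_motifs(config), seq_id=seq_id):
            try:
                models.append(hs.build_dual_orf_model(seq, site))
            except hs.OpenModelError as exc:
                logger.warning("scan: open model at %s:%d (%s)", seq_id, site.start, exc)
    hs.write_site_table(models, outdir / "sites.tsv")
    hs.write_models_gff3(models, outdir / "models.gff3")
    ctx["seqs"] = seqs
    ctx["models"] = models
    ctx["sites"] = [
        {
            "seq_id": m.seq_id,
            "heptamer_start": m.site.start,
            "motif": m.site.motif.name,
            "orf0_start": m.orf0_start,
            "orf0_end": m.orf0_end,
            "orf1_end": m.orf1_end,
        }
        for m in models
    ]


def _stage_ribofs(config: RunConfig, outdir: Path, ctx: dict) -> None:
    estimates = []
    for entry, model in zip(ctx["sites"], ctx["models"]):
        seq = ctx["seqs"][model.seq_id]
        profile = ribo.read_counts_tsv(config.counts, model.seq_id, len(seq))
        est = ribo.fs_efficiency(
            profile, model, config.trim_codons, config.mode, config.region0_end
        )
        estimates.append(est)
        entry["ribo_fs_pct"] = est.efficiency_pct if est.defined else None
    ribo.write_estimates_tsv(estimates, outdir / "ribo_fs.tsv")


def _stage_lucfs(config: RunConfig, outdir: Path, ctx: dict) -> None:
    reps = rq.read_luciferase_tsv(config.luciferase)
    tests = [r for r in reps if r.construct_class == "test"]
    controls = [r for r in reps if r.construct_class == "in_frame_control"]
    result = rq.fs_from_luciferase(tests, controls, config.method)
    rq.write_reporter_tsv({"run": result}, outdir / "reporter.tsv")
    for entry in ctx["sites"]:
        entry["reporter_fs_pct"] = result.efficiency_pct
        entry["reporter_sd_pct"] = result.sd_pct


def _stage_consscan(config: RunConfig, outdir: Path, ctx: dict) -> None:
    aln = cons.read_codon_alignment_fasta(config.alignment)
    stats_list = cons.window_synonymy_scan(aln, config.window)
    cons.write_window_stats_tsv(stats_list, outdir / "conservation.tsv")
    defined = [w for w in stats_list if w.defined]
    if defined:
        best = min(defined, key=lambda w: w.p_value)
        for entry in ctx["sites"]:
            entry["conservation_min_p"] = best.p_value
            entry["conservation_min_p_center"] = best.center_codon
    ctx["conservation"] = stats_list


def _stage_fold(config: RunConfig, outdir: Path, ctx: dict) -> None:
    max_len = max((len(s) for s in ctx["seqs"].values()), default=0)
    track = (
        sp.read_reactivity_tsv(config.reactivity, length=max_len)
        if config.reactivity
        else None
    )
    for k, (entry, model) in enumerate(zip(ctx["sites"], ctx["models"])):
        seq = ctx["seqs"][model.seq_id]
        lo = max(model.orf0_start, model.site.start - FOLD_WINDOW_NT)
        stem = sp.find_best_hairpin(seq, (lo, model.site.start))
        if stem is None:
            entry["hairpin"] = None
            continue
        spacer_nt, spacer_codons = sp.spacer_to_site(stem, model.site)
        entry["hairpin"] = {
            "span": list(stem.span),
            "score": stem.score,
            "n_pairs": stem.n_pairs,
            "spacer_nt": spacer_nt,
            "spacer_codons": spacer_codons,
        }
        sp.write_structure(
            outdir / f"hairpin_{model.seq_id}_{k}.txt", model.seq_id, seq, stem
        )
        if track is not None:
            score = sp.dms_consistency(stem, track)
            entry["hairpin"]["dms_consistency"] = None if math.isnan(score) else score


_STAGE_FUNCS = {
    "scan": _stage_scan,
    "ribofs": _stage_ribofs,
    "lucfs": _stage_lucfs,
    "consscan": _stage_consscan,
    "fold": _stage_fold,
}

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "STAGES"]
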