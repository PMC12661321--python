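"""Dual-luciferase frameshifting efficiencies.

In the dual-luciferase recoding assay a test construct places the firefly
luciferase ORF downstream of the frameshift cassette in the +1 frame, so
firefly signal requires frameshifting, while Renilla luciferase (upstream,
0-frame) reports expression level.  An in-frame control fuses both ORFs in
one frame and defines the 100% point.  The frameshifting efficiency is the
ratio of firefly/Renilla ratios between test and control constructs,
expressed as a percentage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LuciferaseReplicate:
    """One well: firefly and Renilla luminescence readings."""

    sample_id: str
    construct_class: str  # "test" | "in_frame_control"
    firefly: float
    renilla: float

    def __post_init__(self) -> None:
        if self.construct_class not in ("test", "in_frame_control"):
            raise ValueError(f"unknown construct class {self.construct_class!r}")
        if self.firefly < 0:
            raise ValueError(f"{self.sample_id}: negative firefly reading")
        if self.renilla <= 0:
            raise ValueError(f"{self.sample_id}: Renilla reading must be positive")

    @property
    def ratio(self) -> float:
        return self.firefly / self.renilla


@dataclass
class ReporterResult:
    """Efficiency (percent of in-frame control) with a propagated SD."""

    efficiency_pct: float
    sd_pct: float
    n_test: int
    n_control: int


def fs_from_luciferase(
    tests: list[LuciferaseReplicate],
    controls: list[LuciferaseReplicate],
    method: str = "mean_of_ratios",
    n_bootstrap: int = 0,
    rng: np.random.Generator | None = None,
) -> ReporterResult:
    """Frameshifting efficiency as a ratio of luciferase ratios.

    ``mean_of_ratios`` (default) averages per-well firefly/Renilla ratios
    within each class before taking the test/control ratio, matching the
    per-well structure of the assay; ``ratio_of_means`` pools each class's
    summed firefly over summed Renilla first.  The SD is propagated to first
    order from the two class-level coefficients of variation; pass
    ``n_bootstrap > 0`` to replace it with a resampling SD.
    """
    if not tests or not controls:
        raise ValueError("at least one replicate per class is required")
    if method not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError(f"unknown method {method!r}")

    eff = 100.0 * _class_ratio(tests, method) / _class_ratio(controls, method)
    sd = _propagated_sd(tests, controls, eff)
    if n_bootstrap > 0:
        rng = np.random.default_rng() if rng is None else rng
        sd = _bootstrap_sd(tests, controls, method, n_bootstrap, rng)
    return ReporterResult(eff, sd, len(tests), len(controls))


def _class_ratio(reps: list[LuciferaseReplicate], method: str) -> float:
    if method == "mean_of_ratios":
        return float(np.mean([r.ratio for r in reps]))
    return float(sum(r.firefly for r in reps) / sum(r.renilla for r in reps))


def _propagated_sd(tests, controls, eff: float) -> float:
    if len(tests) < 2 or len(controls) < 2:
        return math.nan
    rt = np.array([r.ratio for r in tests])
    rc = np.array([r.ratio for r in controls])
    mt, mc = rt.mean(), rc.mean()
    if mt == 0 or mc == 0:
        return math.nan
    # first-order delta method on the ratio of class means: the class SDs
    # enter as standard errors, so this matches what the bootstrap estimates
    cv2 = (rt.std(ddof=1) / mt) ** 2 / len(rt) + (rc.std(ddof=1) / mc) ** 2 / len(rc)
    return abs(eff) * math.sqrt(cv2)


def _bootstrap_sd(tests, controls, method, n_bootstrap, rng) -> float:
    effs = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        ts = [tests[i] for i in rng.integers(len(tests), size=len(tests))]
        cs = [controls[i] for i in rng.integers(len(controls), size=len(controls))]
        effs[b] = 100.0 * _class_ratio(ts, method) / _class_ratio(cs, method)
    return float(effs.std(ddof=1))


def context_fold_change(
    context_result: ReporterResult, heptamer_result: ReporterResult
) -> float:
    """Fold change of efficiency in a native mRNA context over the bare heptamer.

    Returns NaN (with a warning) when the heptamer-only efficiency is zero.
    """
    if heptamer_result.efficiency_pct == 0:
        logger.warning("context_fold_change: zero heptamer-only efficiency; fold undefined")
        return math.nan
    return context_result.efficiency_pct / heptamer_result.efficiency_pct


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_luciferase_tsv(path) -> list[LuciferaseReplicate]:
    """Read replicates from TSV: sample_id, construct_class, firefly, renilla."""
    df = pd.read_csv(path, sep="\t")
    return [
        LuciferaseReplicate(
            str(r.sample_id), str(r.construct_class), float(r.firefly), float(r.renilla)
        )
        for r in df.itertuples(index=False)
    ]


def write_reporter_tsv(results: dict[str, ReporterResult], path) -> None:
    pd.DataFrame(
        [
            {
                "sample": name,
                "efficiency_pct": res.efficiency_pct,
                "sd_pct": res.sd_pct,
                "n_test": res.n_test,
                "n_control": res.n_control,
            }
            for name, res in results.items()
        ]
    ).to_csv(path, sep="\t", index=False)
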