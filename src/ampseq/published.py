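"""Published grapevine AmpSeq panel summaries and the statistics derived
from them.

The package ships the per-amplicon summary tables of the three published
grapevine panels (flower sex on chr2, Ren2 powdery-mildew resistance on
chr14, acylated anthocyanins on chr3): position, mean read depth over the
380 genotyped individuals, depth CV, count of missing individuals, and the
per-family / pooled association statistics (ANOVA P, marker R^2, minor
allele frequency). These tables are inputs for marker-density and
experiment-level QC summaries; each experiment's panel additionally
contained one amplicon that failed SNP calling (no polymorphism), which the
summaries count as failing every QC threshold.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
import pandas as pd

from .mas import marker_density

#: amplicons designed per trait panel (flower sex + PM = experiment 1,
#: anthocyanins = experiment 2)
PANEL_SIZES = {"flower_sex": 19, "pm_resistance": 12, "anthocyanin": 23}

_FILES = {
    "flower_sex": "flower_sex_panel.tsv",
    "pm_resistance": "pm_resistance_panel.tsv",
    "anthocyanin": "anthocyanin_panel.tsv",
}

EXPERIMENTS = {1: ["flower_sex", "pm_resistance"], 2: ["anthocyanin"]}

SAMPLES_PER_EXPERIMENT = 380
SIGNIFICANCE_NEG_LOG10_P = 2.0  # -log10(P) > 2 counts as significant


def load_panel_summary(trait: str) -> pd.DataFrame:
    """One of the shipped panel summary tables (``flower_sex``,
    ``pm_resistance`` or ``anthocyanin``)."""
    ref = resources.files("ampseq.data") / _FILES[trait]
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NaN"], keep_default_na=False)


def panel_marker_density(trait: str) -> int:
    """Average kb per marker over a panel's summary rows (span / count)."""
    df = load_panel_summary(trait)
    return marker_density(df["pos"].tolist())


def count_significant(p_values, threshold_neg_log10: float = SIGNIFICANCE_NEG_LOG10_P) -> int:
    """Markers whose association P-value clears -log10(P) > threshold;
    NaN (no association detectable) never counts as significant."""
    n = 0
    for p in p_values:
        p = float(p)
        if not math.isnan(p) and (p == 0.0 or -math.log10(p) > threshold_neg_log10):
            n += 1
    return n


def experiment_qc_summary(experiment: int) -> dict[str, float]:
    """Experiment-level amplicon QC derived from the panel summaries.

    Percentages use the number of amplicons tested in the experiment as the
    denominator, counting an amplicon that failed SNP calling (and therefore
    has no summary row) as failing both thresholds. Coverage medians are
    over the amplicons with genotyping data, reported to the nearest fold.
    """
    traits = EXPERIMENTS[experiment]
    frames = [load_panel_summary(t) for t in traits]
    df = pd.concat(frames, ignore_index=True)
    n_designed = sum(PANEL_SIZES[t] for t in traits)
    max_missing = 0.10 * SAMPLES_PER_EXPERIMENT
    n_low_missing = int((df["missing_individuals"] < max_missing).sum())
    n_deep = int((df["mean_depth"] > 50).sum())
    depths = df["mean_depth"].to_numpy(dtype=float)
    return {
        "n_amplicons": n_designed,
        "n_with_data": len(df),
        "pct_missing_below_10": 100.0 * n_low_missing / n_designed,
        "pct_depth_above_50x": 100.0 * n_deep / n_designed,
        "median_coverage": float(math.floor(np.median(depths) + 0.5)),
        "mean_coverage": float(depths.mean()),
    }
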