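"""Published predictor benchmark figures, consumed as input data.

Six chloroplast transit-peptide predictors were benchmarked against
GFP-validated subcellular localizations; the table below carries each
program's sensitivity and precision-style specificity on that dataset,
plus the monocot/eudicot stratified rows for the two programs whose
confusion matrices reconstruct exactly from the printed statistics.
These numbers parameterize simulations (via the precision → FPR
conversion) and reconstruction checks; they are inputs, not results.
"""

from __future__ import annotations

import pandas as pd

from .simulate import precision_to_fpr, simulate_calls
from .targeting import evaluate_workflows

__all__ = [
    "GFP_BENCHMARK",
    "STRATIFIED_ROWS",
    "STRATUM_SIZES",
    "simulated_predictor_panel",
    "workflow_gain",
]

#: (sensitivity, precision-style specificity) per predictor on the
#: GFP-validated benchmark.
GFP_BENCHMARK: dict[str, tuple[float, float]] = {
    "TargetP": (0.67, 0.59),
    "WolfPSORT": (0.72, 0.38),
    "PredSL": (0.57, 0.53),
    "Localizer": (0.68, 0.71),
    "Multiloc2": (0.50, 0.83),
    "PCLR": (0.74, 0.46),
}

#: (positives, negatives) per stratum of the GFP benchmark.
STRATUM_SIZES: dict[str, tuple[int, int]] = {
    "monocot": (161, 640),
    "eudicot": (489, 2432),
}

#: Printed (SE, SP, MCC, ACC) per (stratum, predictor).
STRATIFIED_ROWS: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("monocot", "TargetP"): (0.62, 0.71, 0.59, 0.87),
    ("monocot", "PCLR"): (0.75, 0.56, 0.54, 0.83),
    ("eudicot", "TargetP"): (0.68, 0.56, 0.53, 0.86),
    ("eudicot", "PCLR"): (0.73, 0.43, 0.45, 0.80),
}


def simulated_predictor_panel(
    n_pos: int = 500,
    n_neg: int = 2500,
    rng_seed: int = 0,
    benchmark: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate independent predictor calls at the benchmarked rates.

    Each predictor's precision-style specificity is converted to a
    false-positive rate at the requested prevalence; calls are then
    independent Bernoulli draws.  Returns (calls, truth labels).
    """
    benchmark = benchmark or GFP_BENCHMARK
    index = [f"pos{i}" for i in range(n_pos)] + [f"neg{i}" for i in range(n_neg)]
    truth = pd.DataFrame(
        {"plastid": [i < n_pos for i in range(n_pos + n_neg)]}, index=index
    )
    predictors = [
        (name, se, precision_to_fpr(se, sp, n_pos, n_neg))
        for name, (se, sp) in benchmark.items()
    ]
    calls = simulate_calls(truth, predictors, rng_seed=rng_seed)
    return calls, truth["plastid"]


def workflow_gain(
    n_pos: int = 500,
    n_neg: int = 2500,
    rng_seed: int = 0,
) -> dict[str, float | str]:
    """Best combinatorial vs best standalone workflow on the simulated panel.

    Runs the full exhaustive k-of-n sweep and reports the top MCC among
    multi-predictor workflows against the top standalone program.
    """
    calls, labels = simulated_predictor_panel(n_pos, n_neg, rng_seed)
    table = evaluate_workflows(calls, labels)
    standalone = table[table["threshold"] == 1]
    standalone = standalone[~standalone["predictors"].str.contains(",")]
    combos = table[table["predictors"].str.contains(",")]
    best_single = standalone.loc[standalone["mcc"].idxmax()]
    best_combo = combos.loc[combos["mcc"].idxmax()]
    return {
        "best_standalone": best_single["predictors"],
        "best_standalone_mcc": float(best_single["mcc"]),
        "best_combo": best_combo["workflow"],
        "best_combo_mcc": float(best_combo["mcc"]),
        "mcc_gain": float(best_combo["mcc"] - best_single["mcc"]),
    }
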