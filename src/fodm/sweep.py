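"""Convention sensitivity sweep.

Published RD/K tables in this field depend on conventions that reports do
not always state (hydrophobicity scale, sigma rule, interaction cutoff,
self-term).  ``sensitivity_sweep`` recomputes a unit under each combination
of bundled scales and sigma rules and, given printed reference values,
ranks conventions by distance to them.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .structure_io import builtin_scale
from .units import AnalysisParams, UnitSelection, analyze_individual

SCALES = ("kyte_doolittle", "fauchere_pliska")
SIGMA_RULES = ("extent3", "extent6", "std")


def sensitivity_sweep(
    source,
    sel: UnitSelection | None = None,
    printed_rd: float | None = None,
    printed_k: float | None = None,
    base_params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """RD/K for every scale x sigma-rule combination, optionally ranked.

    Returns a frame with columns scale, sigma_rule, RD, K (and, when
    printed values are given, the absolute deviations and a combined score
    by which rows are sorted ascending — the first row is the
    closest-matching convention).
    """
    base = base_params or AnalysisParams()
    rows = []
    for scale_name in SCALES:
        scale = builtin_scale(scale_name)
        for rule in SIGMA_RULES:
            params = replace(base, scale=scale, sigma_rule=rule)
            rec = analyze_individual(source, sel, params)
            row = {"scale": scale_name, "sigma_rule": rule,
                   "RD": rec.rd, "K": rec.k}
            if printed_rd is not None:
                row["dRD"] = abs(rec.rd - printed_rd)
            if printed_k is not None:
                row["dK"] = abs(rec.k - printed_k)
            rows.append(row)
    df = pd.DataFrame(rows)
    if printed_rd is not None or printed_k is not None:
        score = df.get("dRD", 0.0) + 0.0
        if "dK" in df:
            score = score + 0.1 * df["dK"]
        df = df.assign(score=score).sort_values("score").reset_index(drop=True)
    return df
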