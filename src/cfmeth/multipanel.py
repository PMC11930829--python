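"""Multi-panel tumor-origin typing over PAC/HCC/CRC/GC marker panels.

Each plasma sample is evaluated against every cancer type's calibrated
panel.  A sample is non-cancerous only when every panel is negative; a
single positive panel names the cancer type; when several panels are
positive the call goes to the panel with the highest fraction of positive
markers.  Fractions are compared as exact rationals (positive count over
panel size), so a tie is an exact arithmetic tie and yields an
indeterminate call.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .panel import MarkerPanel, PanelEvaluation, evaluate_sample
from .types import MethylationMatrix


@dataclass(frozen=True)
class TypingResult:
    per_panel: dict[str, tuple[PanelEvaluation, bool]]
    call: str  # cancer type, "non_cancer" or "indeterminate"
    tie_break_used: bool


def evaluate_panels(
    sample_values, panels: list[MarkerPanel]
) -> dict[str, tuple[PanelEvaluation, bool]]:
    """Per-panel evaluation and positivity flag (count > cutoff, strictly)."""
    out: dict[str, tuple[PanelEvaluation, bool]] = {}
    for panel in panels:
        if panel.count_cutoff is None:
            raise ValueError(f"panel {panel.cancer!r} has no calibrated count_cutoff")
        if panel.cancer in out:
            raise ValueError(f"duplicate panel for cancer {panel.cancer!r}")
        evaluation = evaluate_sample(sample_values, panel)
        out[panel.cancer] = (evaluation, evaluation.positive_count > panel.count_cutoff)
    return out


def typing_decision(per_panel: dict[str, tuple[PanelEvaluation, bool]]) -> TypingResult:
    """Final origin call from the per-panel evaluations.

    No positive panel -> non_cancer.  Exactly one -> that cancer.  Several
    -> the flagged panel with the largest exact positive fraction
    (tie_break_used); an exact fraction tie among the leaders is
    indeterminate.
    """
    flagged = sorted(c for c, (_, flag) in per_panel.items() if flag)
    if not flagged:
        return TypingResult(per_panel=dict(per_panel), call="non_cancer", tie_break_used=False)
    if len(flagged) == 1:
        return TypingResult(per_panel=dict(per_panel), call=flagged[0], tie_break_used=False)
    best = max(per_panel[c][0].fraction_positive for c in flagged)
    leaders = [c for c in flagged if per_panel[c][0].fraction_positive == best]
    call = leaders[0] if len(leaders) == 1 else "indeterminate"
    return TypingResult(per_panel=dict(per_panel), call=call, tie_break_used=True)


def type_sample(sample_values, panels: list[MarkerPanel]) -> TypingResult:
    return typing_decision(evaluate_panels(sample_values, panels))


def type_samples(matrix: MethylationMatrix, panels: list[MarkerPanel]) -> pd.DataFrame:
    """Type every sample in a cohort; one row per sample.

    Columns: the final call, whether the fraction tie-break was exercised,
    and per-cancer count / fraction / flag triplets.
    """
    rows = []
    for sample_id in matrix.sample_ids:
        result = type_sample(matrix.values.loc[sample_id], panels)
        row: dict = {"sample_id": sample_id, "call": result.call,
                     "tie_break_used": result.tie_break_used}
        for cancer, (evaluation, flag) in sorted(result.per_panel.items()):
            row[f"{cancer}_count"] = evaluation.positive_count
            row[f"{cancer}_fraction"] = float(evaluation.fraction_positive)
            row[f"{cancer}_flag"] = flag
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
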