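"""Stress-level and autonomic-balance classification, plus SRI scoring.

SDNN is used as the overall stress-coping index and the LF/HF ratio as
the sympatho-vagal balance index.  Bin edges follow the published
clinical mapping; where the printed ranges overlap at 35 and 50 ms, the
boundary value is assigned to the less severe category (50 -> NORMAL,
35 -> NORMAL), and both 0.5 and 2.0 belong to the BALANCED band.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "StressLevel",
    "AutonomicBalance",
    "StressAssessment",
    "classify_sdnn",
    "classify_lfhf",
    "score_sri",
    "assess",
    "SRI_SEVERE_THRESHOLD",
]

#: SRI totals strictly above this are interpreted as severe stress
SRI_SEVERE_THRESHOLD = 56
SRI_N_ITEMS = 22


class StressLevel(str, enum.Enum):
    NON_STRESSED = "NON_STRESSED"   # SDNN > 50 ms
    NORMAL = "NORMAL"               # 35-50 ms
    HIGH = "HIGH"                   # 20-35 ms
    VERY_HIGH = "VERY_HIGH"         # < 20 ms


class AutonomicBalance(str, enum.Enum):
    HYPER_SYMPATHETIC = "HYPER_SYMPATHETIC"          # LF/HF > 2.0, acute stress
    BALANCED = "BALANCED"                            # 0.5-2.0
    HYPER_PARASYMPATHETIC = "HYPER_PARASYMPATHETIC"  # < 0.5, chronic stress


@dataclass(frozen=True)
class StressAssessment:
    sdnn_level: StressLevel
    balance: AutonomicBalance
    sdnn: float
    lf_hf: float

    def to_dict(self) -> dict:
        return {
            "sdnn_level": self.sdnn_level.value,
            "balance": self.balance.value,
            "sdnn": self.sdnn,
            "lf_hf": self.lf_hf,
        }


def classify_sdnn(sdnn_ms: float) -> StressLevel:
    """Map SDNN (ms) to a stress level.

    Bins: (50, inf) NON_STRESSED; [35, 50] NORMAL; [20, 35) HIGH;
    [0, 20) VERY_HIGH.
    """
    if sdnn_ms < 0:
        raise ValueError(f"SDNN must be non-negative, got {sdnn_ms}")
    if sdnn_ms > 50:
        return StressLevel.NON_STRESSED
    if sdnn_ms >= 35:
        return StressLevel.NORMAL
    if sdnn_ms >= 20:
        return StressLevel.HIGH
    return StressLevel.VERY_HIGH


def classify_lfhf(ratio: float) -> AutonomicBalance:
    """Map the LF/HF ratio to an autonomic-balance category.

    Bins: (2.0, inf) HYPER_SYMPATHETIC; [0.5, 2.0] BALANCED;
    [0, 0.5) HYPER_PARASYMPATHETIC.
    """
    if ratio < 0:
        raise ValueError(f"LF/HF ratio must be non-negative, got {ratio}")
    if ratio > 2.0:
        return AutonomicBalance.HYPER_SYMPATHETIC
    if ratio >= 0.5:
        return AutonomicBalance.BALANCED
    return AutonomicBalance.HYPER_PARASYMPATHETIC


def score_sri(items) -> tuple[int, bool]:
    """Score a 22-item stress-response questionnaire.

    Each item is an integer 0-4 ("not at all" .. "absolutely"); the
    total ranges 0-88 and totals strictly greater than 56 flag severe
    stress.
    """
    items = list(items)
    if len(items) != SRI_N_ITEMS:
        raise ValueError(f"expected {SRI_N_ITEMS} items, got {len(items)}")
    for i, v in enumerate(items):
        if not (isinstance(v, (int,)) or float(v).is_integer()) or not 0 <= int(v) <= 4:
            raise ValueError(f"item {i} out of range 0-4: {v!r}")
    total = int(sum(int(v) for v in items))
    return total, total > SRI_SEVERE_THRESHOLD


def assess(metrics) -> StressAssessment:
    """Compose the SDNN and LF/HF classifiers into one assessment."""
    return StressAssessment(
        sdnn_level=classify_sdnn(metrics.sdnn),
        balance=classify_lfhf(metrics.lf_hf),
        sdnn=float(metrics.sdnn),
        lf_hf=float(metrics.lf_hf),
    )
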