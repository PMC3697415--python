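"""Confusion counts, sensitivity/specificity, and dose-level breakdowns.

Convention: pure samples are the positive class (the class model is built to
accept them), adulterated samples are negative.  Hence

    sensitivity = TP / (TP + FN)   (pure samples accepted)
    specificity = TN / (TN + FP)   (adulterated samples rejected)

The per-group table counts accepted samples per (adulterant, doping level);
an adulterant's *detection level* is the smallest designed dose L such that
no sample at L or at any higher dose was accepted — the operational reading
of "adulteration at L can be safely detected".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .exceptions import MetadataError, MetricUndefinedError
from .ocpls import OCPLSModel, PredictionResult
from .spectra_io import SampleMeta

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion",
    "sens_spec",
    "group_table",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN on pure samples, TN/FP on adulterated samples."""

    TP: int = 0
    FN: int = 0
    TN: int = 0
    FP: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_pure(self) -> int:
        return self.TP + self.FN

    @property
    def n_adulterated(self) -> int:
        return self.TN + self.FP


def _paired(
    results: Sequence[PredictionResult], meta: Sequence[SampleMeta]
) -> list[tuple[PredictionResult, SampleMeta]]:
    if len(results) != len(meta):
        raise MetadataError(
            f"{len(results)} predictions but {len(meta)} metadata records"
        )
    for r, m in zip(results, meta):
        if r.sample_id != m.sample_id:
            raise MetadataError(
                f"prediction/metadata order mismatch at {r.sample_id} vs {m.sample_id}"
            )
    return list(zip(results, meta))


def confusion(
    results: Sequence[PredictionResult], meta: Sequence[SampleMeta]
) -> ConfusionCounts:
    """Tally accept/reject decisions against true class labels."""
    tp = fn = tn = fp = 0
    for r, m in _paired(results, meta):
        if m.is_pure:
            tp += r.accepted
            fn += not r.accepted
        else:
            fp += r.accepted
            tn += not r.accepted
    return ConfusionCounts(TP=tp, FN=fn, TN=tn, FP=fp)


def sens_spec(counts: ConfusionCounts) -> tuple[float, float]:
    """Exact sensitivity and specificity ratios from confusion counts."""
    if counts.n_pure == 0:
        raise MetricUndefinedError("sensitivity undefined: no pure samples")
    if counts.n_adulterated == 0:
        raise MetricUndefinedError("specificity undefined: no adulterated samples")
    return counts.TP / counts.n_pure, counts.TN / counts.n_adulterated


def group_table(
    results: Sequence[PredictionResult], meta: Sequence[SampleMeta]
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Accepted-count table per (adulterant, doping level) + detection levels.

    Returns a DataFrame with columns (adulterant, doping_level, n,
    n_accepted), levels ascending within each adulterant, and a dict mapping
    each adulterant to its detection level (None when even the highest dose
    still had accepted samples).
    """
    pairs = [(r, m) for r, m in _paired(results, meta) if not m.is_pure]
    if not pairs:
        raise MetricUndefinedError("group table requires adulterated results")
    counter: dict[tuple[str, float], list[int]] = {}
    for r, m in pairs:
        key = (m.adulterant, m.doping_level)
        cell = counter.setdefault(key, [0, 0])
        cell[0] += 1
        cell[1] += r.accepted
    rows = [
        {"adulterant": a, "doping_level": lvl, "n": n, "n_accepted": acc}
        for (a, lvl), (n, acc) in counter.items()
    ]
    table = pd.DataFrame(rows).sort_values(
        ["adulterant", "doping_level"], ignore_index=True
    )
    detection: dict[str, float | None] = {}
    for adulterant, sub in table.groupby("adulterant"):
        sub = sub.sort_values("doping_level", ascending=False)
        level: float | None = None
        for _, row in sub.iterrows():  # descending: extend the clean suffix
            if row["n_accepted"] == 0:
                level = float(row["doping_level"])
            else:
                break
        detection[str(adulterant)] = level
    return table, detection


@dataclass(frozen=True)
class EvaluationReport:
    """Everything the study reports for one preprocessing variant."""

    preprocessing: str
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    per_group: pd.DataFrame
    detection_levels: dict[str, float | None]
    n_components: int
    mu_e: float
    sigma_e: float

    def __post_init__(self) -> None:
        # self-consistency: the per-group margin must reproduce TN + FP
        if int(self.per_group["n"].sum()) != self.counts.n_adulterated:
            raise ValueError("per-group counts do not sum to the adulterated margin")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "preprocessing": self.preprocessing,
                    "n_components": self.n_components,
                    "mu_e": self.mu_e,
                    "sigma_e": self.sigma_e,
                    "TP": self.counts.TP,
                    "FN": self.counts.FN,
                    "TN": self.counts.TN,
                    "FP": self.counts.FP,
                    "sensitivity": self.sensitivity,
                    "specificity": self.specificity,
                }
            ]
        )

    def to_text(self) -> str:
        c = self.counts
        lines = [
            f"OCPLS evaluation — preprocessing: {self.preprocessing}",
            f"  latent variables: {self.n_components}   "
            f"mu_e = {self.mu_e:.6f}   sigma_e = {self.sigma_e:.6f}",
            f"  sensitivity = {self.sensitivity:.3f} ({c.TP}/{c.n_pure})   "
            f"specificity = {self.specificity:.3f} ({c.TN}/{c.n_adulterated})",
            "  accepted per (adulterant, level):",
        ]
        for _, row in self.per_group.iterrows():
            lines.append(
                f"    {row['adulterant']}  {row['doping_level']:.3f}  "
                f"{int(row['n_accepted'])}/{int(row['n'])} accepted"
            )
        for a, lvl in sorted(self.detection_levels.items()):
            shown = "none" if lvl is None else f"{lvl:.3f}"
            lines.append(f"  detection level {a}: {shown}")
        return "\n".join(lines)


def evaluate_predictions(
    results: Sequence[PredictionResult],
    meta: Sequence[SampleMeta],
    model: OCPLSModel,
) -> EvaluationReport:
    """Assemble the full report for one fitted model's test predictions."""
    counts = confusion(results, meta)
    sens, spec = sens_spec(counts)
    table, detection = group_table(results, meta)
    return EvaluationReport(
        preprocessing=model.preprocessing,
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        per_group=table,
        detection_levels=detection,
        n_components=model.n_components,
        mu_e=model.mu_e,
        sigma_e=model.sigma_e,
    )
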