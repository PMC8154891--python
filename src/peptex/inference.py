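"""Cycle assembly: closure inference of kd1, fold-changes, summary tables.

The chaperone-binding constant kd1 cannot be measured directly (empty
MHC-I is unstable without the chaperone), so it is inferred from the
other three steps via detailed balance, ``kd1 = kd2 * kd3 / kd4``.
Uncertainties propagate to first order on the log scale: relative
variances of the three measured constants add.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = ["Measurement", "StepFits", "CycleSummary", "infer_kd1", "fold_change", "summarize"]


@dataclass(frozen=True)
class Measurement:
    """A fitted value with its standard error (same units)."""

    value: float
    stderr: float = 0.0

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("measured constants must be positive")
        if not (self.stderr >= 0):
            raise ValueError("standard errors must be non-negative")

    @property
    def rel_var(self) -> float:
        return (self.stderr / self.value) ** 2


@dataclass(frozen=True)
class StepFits:
    """Per-condition fitted constants for cycle steps 2-4 (+ stoichiometries)."""

    peptide: str
    variant: str
    kd2_app: Measurement
    kd3: Measurement
    kd4: Measurement
    n2: float | None = None
    n3: float | None = None
    n4: float | None = None


def infer_kd1(kd2_app: Measurement, kd3: Measurement, kd4: Measurement) -> Measurement:
    """Closure-inferred kd1 with log-propagated uncertainty."""
    value = kd2_app.value * kd3.value / kd4.value
    rel = math.sqrt(kd2_app.rel_var + kd3.rel_var + kd4.rel_var)
    return Measurement(value, value * rel)


@dataclass(frozen=True)
class CycleSummary:
    """All fitted and inferred constants for one (peptide, variant) pair."""

    peptide: str
    variant: str
    kd1_app: Measurement
    kd2_app: Measurement
    kd3: Measurement
    kd4: Measurement
    n2: float | None = None
    n3: float | None = None
    n4: float | None = None

    @classmethod
    def from_fits(cls, fits: StepFits) -> "CycleSummary":
        return cls(
            peptide=fits.peptide,
            variant=fits.variant,
            kd1_app=infer_kd1(fits.kd2_app, fits.kd3, fits.kd4),
            kd2_app=fits.kd2_app,
            kd3=fits.kd3,
            kd4=fits.kd4,
            n2=fits.n2,
            n3=fits.n3,
            n4=fits.n4,
        )

    def step(self, name: str) -> Measurement:
        try:
            return {"kd1": self.kd1_app, "kd2": self.kd2_app, "kd3": self.kd3, "kd4": self.kd4}[name]
        except KeyError:
            raise KeyError(f"unknown cycle step {name!r}") from None


def fold_change(
    summaries: Mapping[tuple[str, str], CycleSummary],
    step: str,
    peptide: str,
    variant: str = "dG24R36",
    reference: str = "WT",
) -> Measurement:
    """Variant-over-reference ratio of one step constant, log-propagated se."""
    try:
        var = summaries[(peptide, variant)].step(step)
        ref = summaries[(peptide, reference)].step(step)
    except KeyError as exc:
        raise KeyError(f"missing cycle summary for {peptide!r}: {exc}") from None
    ratio = var.value / ref.value
    rel = math.sqrt(var.rel_var + ref.rel_var)
    return Measurement(ratio, ratio * rel)


def summarize(summaries: Mapping[tuple[str, str], CycleSummary]) -> pd.DataFrame:
    """Long-form table, one row per (peptide, step, variant), values in nM.

    Mirrors the layout of the measured-constant table: value, standard
    error and observed stoichiometry per condition, with kd1 marked as
    inferred (no stoichiometry).
    """
    rows = []
    for (pep, variant), s in sorted(summaries.items()):
        for step_name, meas, n in (
            ("kd1_app", s.kd1_app, None),
            ("kd2_app", s.kd2_app, s.n2),
            ("kd3", s.kd3, s.n3),
            ("kd4", s.kd4, s.n4),
        ):
            rows.append(
                {
                    "peptide": pep,
                    "variant": variant,
                    "step": step_name,
                    "kd_nM": meas.value / 1e-9,
                    "kd_se_nM": meas.stderr / 1e-9,
                    "n_value": n,
                    "inferred": step_name == "kd1_app",
                }
            )
    return pd.DataFrame(rows)
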