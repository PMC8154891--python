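"""End-to-end analysis pipeline over a synthetic assay bundle.

``run_pipeline`` chains the stages: generate every assay input with known
ground truth, refit each titration/competition/melt from the files on
disk, assemble the per-step fits into thermodynamic-cycle summaries with
closure-inferred kd1, and report fold-changes between chaperone variants.
The pipeline is deterministic given the config seed and is driven from
Python or from a YAML config file; the report records every constant,
closure residual and recovery check.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import dsf, fp, itc, synth
from .inference import CycleSummary, Measurement, StepFits, fold_change, summarize

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Seeds, noise levels and output location for one pipeline run."""

    out_dir: str = "pipeline_out"
    seed: int = 42
    replicates: int = 3
    noiseless: bool = False
    peptides: tuple[str, ...] = ("TAX8", "TAX9", "KLL15")
    variants: tuple[str, ...] = ("WT", "dG24R36")
    itc_noise_ucal: float = 0.1
    fp_noise_mp: float = 2.0
    dsf_noise_frac: float = 0.02
    #: relative tolerances for the recovery checks in the report
    tolerances: dict = field(default_factory=lambda: {"kd3": 0.15, "kd4": 0.25, "tm_C": 0.5})

    def generator_config(self) -> synth.GeneratorConfig:
        noise = 0.0 if self.noiseless else 1.0
        return synth.GeneratorConfig(
            seed=self.seed,
            replicates=1 if self.noiseless else self.replicates,
            itc_noise_ucal=noise * self.itc_noise_ucal,
            fp_noise_mp=noise * self.fp_noise_mp,
            dsf_noise_frac=noise * self.dsf_noise_frac,
            peptides=self.peptides,
            variants=self.variants,
        )


def load_config(path) -> PipelineConfig:
    """Read a pipeline config from YAML (keys mirror the dataclass fields)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("peptides", "variants"):
        if key in data:
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def _median_fit(values: list[float]) -> Measurement:
    arr = np.array(values, float)
    se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return Measurement(float(np.median(arr)), se)


def _fit_itc_step(out: Path, step: str, pep: str, variant: str, reps: int) -> tuple[Measurement, float]:
    mac = {"KD2": 15e-6, "KD3": 15e-6, "KD4": 15e-6}[step]
    window = "auto" if step == "KD4" else None
    kds, ns = [], []
    for rep in range(1, reps + 1):
        path = out / f"itc_{step.lower()}_{pep}_{variant}_rep{rep}.csv"
        iso = itc.Isotherm.from_csv(path)
        result = itc.fit_one_site(iso, cell_macromolecule=mac, window=window)
        kds.append(result.kd)
        ns.append(result.n)
    return _median_fit(kds), float(np.median(ns))


def _fit_fp_ic50(out: Path, regime: str, pep: str, variant: str, reps: int) -> Measurement:
    values = []
    for rep in range(1, reps + 1):
        curve = fp.PolarizationCurve.from_csv(out / f"fp_{regime}_{pep}_{variant}_rep{rep}.csv")
        values.append(fp.fit_ic50(curve).ic50)
    return _median_fit(values)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and return (and write) the machine-readable report."""
    out = Path(config.out_dir)
    gen = config.generator_config()
    reps = gen.replicates

    log.info("stage synth: seed=%d out=%s", config.seed, out)
    try:
        synth.generate_assay_bundle(gen, out)
    except Exception as exc:
        raise PipelineError(f"stage synth failed: {exc}") from exc

    report: dict[str, Any] = {
        "config": {**asdict(config), "generator_replicates": reps},
        "cycles": {},
        "fold_changes": {},
        "dsf": {},
        "checks": {},
    }

    summaries: dict[tuple[str, str], CycleSummary] = {}
    presets = synth.table1_presets()
    for variant in config.variants:
        for pep in config.peptides:
            key = f"{pep}/{variant}"
            try:
                kd2, n2 = _fit_itc_step(out, "KD2", pep, variant, reps)
                kd3, n3 = _fit_itc_step(out, "KD3", pep, variant, reps)
                kd4, n4 = _fit_itc_step(out, "KD4", pep, variant, reps)
            except Exception as exc:
                raise PipelineError(f"stage itc-fit failed for {key}: {exc}") from exc
            fits = StepFits(pep, variant, kd2_app=kd2, kd3=kd3, kd4=kd4, n2=n2, n3=n3, n4=n4)
            summary = CycleSummary.from_fits(fits)
            summaries[(pep, variant)] = summary

            try:
                ic50_sub = _fit_fp_ic50(out, "sub", pep, variant, reps)
                ic50_stoich = _fit_fp_ic50(out, "stoich", pep, variant, reps)
            except Exception as exc:
                raise PipelineError(f"stage fp-fit failed for {key}: {exc}") from exc

            truth = presets[(pep, variant)]
            closure_resid = summary.kd1_app.value * summary.kd4.value / (
                summary.kd2_app.value * summary.kd3.value
            ) - 1.0
            report["cycles"][key] = {
                "kd1_app_nM": summary.kd1_app.value / 1e-9,
                "kd1_app_se_nM": summary.kd1_app.stderr / 1e-9,
                "kd2_app_nM": summary.kd2_app.value / 1e-9,
                "kd3_nM": summary.kd3.value / 1e-9,
                "kd4_nM": summary.kd4.value / 1e-9,
                "n2": n2,
                "n3": n3,
                "n4": n4,
                "ic50_sub_nM": ic50_sub.value / 1e-9,
                "ic50_stoich_nM": ic50_stoich.value / 1e-9,
                "closure_residual": closure_resid,
                "truth_kd2_nM": truth.kd2 / 1e-9,
                "truth_kd3_nM": truth.kd3 / 1e-9,
                "truth_kd4_nM": truth.kd4 / 1e-9,
                "truth_kd1_nM": truth.closure_kd1 / 1e-9,
            }

    log.info("stage dsf-fit")
    for pep, tm_true in synth.TM_BY_PEPTIDE.items():
        tms = []
        for rep in range(1, reps + 1):
            curve = dsf.MeltCurve.from_csv(out / f"dsf_{pep}_rep{rep}.csv")
            tms.append(dsf.fit_tm(curve).tm)
        report["dsf"][pep] = {"tm_C": float(np.median(tms)), "truth_tm_C": tm_true}

    # fold-changes between chaperone variants, per peptide and step
    if set(config.variants) >= {"WT", "dG24R36"}:
        for pep in config.peptides:
            for step in ("kd1", "kd2", "kd3", "kd4"):
                m = fold_change(summaries, step, pep)
                report["fold_changes"][f"{pep}/{step}"] = {"ratio": m.value, "se": m.stderr}
            sub_fold = report["cycles"][f"{pep}/dG24R36"]["ic50_sub_nM"] / report["cycles"][f"{pep}/WT"]["ic50_sub_nM"]
            st_fold = report["cycles"][f"{pep}/dG24R36"]["ic50_stoich_nM"] / report["cycles"][f"{pep}/WT"]["ic50_stoich_nM"]
            report["fold_changes"][f"{pep}/ic50_sub"] = {"ratio": sub_fold}
            report["fold_changes"][f"{pep}/ic50_stoich"] = {"ratio": st_fold}

    # recovery checks against configured tolerances
    tol = config.tolerances
    checks = report["checks"]
    for key, cyc in report["cycles"].items():
        checks[f"{key}/kd3"] = abs(cyc["kd3_nM"] / cyc["truth_kd3_nM"] - 1) <= tol["kd3"]
        checks[f"{key}/kd4"] = abs(cyc["kd4_nM"] / cyc["truth_kd4_nM"] - 1) <= tol["kd4"]
    for pep, entry in report["dsf"].items():
        checks[f"dsf/{pep}"] = abs(entry["tm_C"] - entry["truth_tm_C"]) <= tol["tm_C"]
    report["passed"] = all(checks.values())

    summarize(summaries).to_csv(out / "cycle_summary.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
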