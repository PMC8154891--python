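"""Synthetic data generation for the full analysis pipeline.

Every input the package consumes — calorimetric isotherms, polarization
plates, thermal melts and selection count tables — can be generated here
with declared ground truth and bit-reproducible seeding, so all downstream
stages are testable without any external dataset.

The named affinity presets are the measured dissociation constants for
three HLA-A*02:01 peptides (TAX8, TAX9 and the 15-mer KLL15) bound with
either wild-type TAPBPR or the loop-deletion variant dG24-R36, with the
chaperone-binding constant kd1 completed by thermodynamic closure.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import dsf, fp, itc
from .cycle import PeptideAffinities
from .screen import AA_ALPHABET, VariantCount

__all__ = [
    "GeneratorConfig",
    "TABLE_CONSTANTS",
    "TM_BY_PEPTIDE",
    "DEFAULT_ENTHALPIES",
    "table1_presets",
    "preset",
    "preset_kd1",
    "generate_assay_bundle",
    "generate_ssm_library",
]

NM = 1e-9
UM = 1e-6

#: measured constants (value, standard error; molar) per peptide and
#: chaperone variant: kd2 is the apparent peptide/empty-MHC constant, kd3 the
#: pMHC-I/chaperone constant, kd4 the peptide/(MHC-I/chaperone) constant
TABLE_CONSTANTS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "WT": {
        "TAX8": {"kd2": (326 * NM, 14 * NM), "kd3": (2.6 * UM, 0.5 * UM), "kd4": (22.7 * UM, 8.2 * UM)},
        "TAX9": {"kd2": (40.2 * NM, 6.5 * NM), "kd3": (1.9 * UM, 0.7 * UM), "kd4": (2.5 * UM, 0.8 * UM)},
        "KLL15": {"kd2": (383 * NM, 22 * NM), "kd3": (2.2 * UM, 0.5 * UM), "kd4": (21.6 * UM, 7.0 * UM)},
    },
    "dG24R36": {
        "TAX8": {"kd2": (316 * NM, 19 * NM), "kd3": (2.4 * UM, 0.6 * UM), "kd4": (54.4 * UM, 9.4 * UM)},
        "TAX9": {"kd2": (42.6 * NM, 8.3 * NM), "kd3": (1.8 * UM, 0.3 * UM), "kd4": (7.3 * UM, 0.7 * UM)},
        "KLL15": {"kd2": (334 * NM, 20 * NM), "kd3": (2.1 * UM, 0.3 * UM), "kd4": (49.5 * UM, 8.6 * UM)},
    },
}

#: melting temperatures (degC) of the TAX-length pMHC-I series
TM_BY_PEPTIDE = {"TAX8": 43.2, "TAX9": 62.9, "TAX10": 58.9, "TAX12": 53.2}

#: default per-step binding enthalpies (kcal/mol) for forward ITC simulation:
#: peptide burial in the groove is strongly exothermic (dh2), the
#: protein-protein steps less so, and chaperone association with empty MHC-I
#: is taken as largely entropy-driven (small dh1); dh4 follows from the Hess
#: closure dh1 + dh4 = dh2 + dh3
DEFAULT_ENTHALPIES = {"dh2": -10.0, "dh3": -8.0, "dh4": -16.0}
DEFAULT_DH1 = DEFAULT_ENTHALPIES["dh2"] + DEFAULT_ENTHALPIES["dh3"] - DEFAULT_ENTHALPIES["dh4"]


def table1_presets() -> dict[tuple[str, str], PeptideAffinities]:
    """All six (peptide, chaperone-variant) measured constant sets.

    Each entry carries the default enthalpies so it can drive titration
    simulation directly; kd1 per set is available via ``.closure_kd1``.
    """
    out = {}
    for variant, peptides in TABLE_CONSTANTS.items():
        for pep, kds in peptides.items():
            out[(pep, variant)] = PeptideAffinities(
                peptide_id=pep,
                kd2=kds["kd2"][0],
                kd3=kds["kd3"][0],
                kd4=kds["kd4"][0],
                **DEFAULT_ENTHALPIES,
            )
    return out


def preset(peptide: str, variant: str = "WT") -> PeptideAffinities:
    """One named constant set, e.g. ``preset("TAX9", "dG24R36")``."""
    try:
        return table1_presets()[(peptide, variant)]
    except KeyError:
        raise KeyError(f"no preset for peptide {peptide!r} with variant {variant!r}") from None


def preset_kd1(peptide: str, variant: str = "WT") -> float:
    """The closure-inferred chaperone-binding constant for a preset."""
    return preset(peptide, variant).closure_kd1


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth and noise levels for one synthetic bundle."""

    seed: int = 0
    replicates: int = 3
    itc_noise_ucal: float = 0.1
    fp_noise_mp: float = 2.0
    dsf_noise_frac: float = 0.02
    peptides: Sequence[str] = ("TAX8", "TAX9", "KLL15")
    variants: Sequence[str] = ("WT", "dG24R36")
    itc_steps: Sequence[str] = ("KD2", "KD3", "KD4")
    depth_pre: int = 100_000
    depth_post: int = 100_000

    def __post_init__(self):
        if self.depth_pre <= 0 or self.depth_post <= 0:
            raise ValueError("sequencing depths must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def _child_seed(root: int, *tokens) -> int:
    # deterministic per-output seed below 2^31 (crc32 is process-independent,
    # unlike the builtin hash)
    key = zlib.crc32("/".join(map(str, tokens)).encode())
    ss = np.random.SeedSequence([root, key])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_assay_bundle(config: GeneratorConfig, out_dir) -> dict[str, list[str]]:
    """Write ITC, FP and DSF CSVs for every configured condition.

    Identical configs produce byte-identical files.  Returns the written
    paths grouped by assay, and dumps the ground truth alongside them so
    recovery can be asserted downstream.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[str]] = {"itc": [], "fp": [], "dsf": [], "truth": []}

    for variant in config.variants:
        for pep in config.peptides:
            if pep not in TABLE_CONSTANTS[variant]:
                continue
            aff = preset(pep, variant)
            kd1 = aff.closure_kd1
            for step in config.itc_steps:
                protocol = itc.preset_protocol(step, pep)
                for rep in range(1, config.replicates + 1):
                    iso = itc.simulate_titration(
                        protocol,
                        kd1,
                        [aff],
                        dh1=DEFAULT_DH1,
                        noise_sd=config.itc_noise_ucal,
                        seed=_child_seed(config.seed, "itc", variant, pep, step, rep),
                    )
                    path = out / f"itc_{step.lower()}_{pep}_{variant}_rep{rep}.csv"
                    iso.to_csv(path)
                    written["itc"].append(str(path))

            for regime, maker in (("sub", fp.CompetitionAssay.substoichiometric),
                                  ("stoich", fp.CompetitionAssay.stoichiometric)):
                assay = maker(pep)
                for rep in range(1, config.replicates + 1):
                    curve = fp.simulate_competition(
                        assay,
                        kd1,
                        tracer_aff=preset("TAX9", variant),
                        competitor_aff=aff,
                        noise_sd=config.fp_noise_mp,
                        seed=_child_seed(config.seed, "fp", variant, pep, regime, rep),
                    )
                    path = out / f"fp_{regime}_{pep}_{variant}_rep{rep}.csv"
                    curve.to_csv(path, replicate=rep)
                    written["fp"].append(str(path))

    for pep, tm in TM_BY_PEPTIDE.items():
        for rep in range(1, config.replicates + 1):
            curve = dsf.simulate_melt(
                tm,
                noise_sd=config.dsf_noise_frac * 100.0,
                seed=_child_seed(config.seed, "dsf", pep, rep),
            )
            path = out / f"dsf_{pep}_rep{rep}.csv"
            curve.to_csv(path, replicate=rep)
            written["dsf"].append(str(path))

    truth_path = out / "ground_truth.json"
    truth = {
        "seed": config.seed,
        "enthalpies": {**DEFAULT_ENTHALPIES, "dh1": DEFAULT_DH1},
        "tm_C": TM_BY_PEPTIDE,
        "constants_M": {
            variant: {
                pep: {k: v[0] for k, v in kds.items()}
                | {"kd1": preset(pep, variant).closure_kd1}
                for pep, kds in peptides.items()
            }
            for variant, peptides in TABLE_CONSTANTS.items()
        },
    }
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    written["truth"].append(str(truth_path))
    return written


def generate_ssm_library(
    positions: Sequence[int],
    wildtype: str,
    effect_map: Mapping[tuple[int, str], float] | None = None,
    depth_pre: int = 100_000,
    depth_post: int = 100_000,
    seed: int | None = None,
    first_position: int | None = None,
) -> list[VariantCount]:
    """Single-substitution library counts under a latent-fitness selection.

    One row per (position, substitution) over the 20 non-wild-type codes
    (19 amino acids plus stop), plus one wild-type row per position for
    normalisation.  Pre-selection frequencies are uniform; post-selection
    frequencies are proportional to ``pre * 2**fitness`` with fitness 0
    where the effect map is silent, and counts are drawn multinomially at
    the requested depths.
    """
    if not positions:
        raise ValueError("positions must be non-empty")
    if depth_pre <= 0 or depth_post <= 0:
        raise ValueError("sequencing depth must be positive")
    first = first_position if first_position is not None else min(positions)
    effect_map = dict(effect_map or {})

    entries: list[tuple[int, str, float]] = []
    for pos in positions:
        wt_aa = wildtype[pos - first]
        entries.append((pos, wt_aa, 0.0))
        for aa in AA_ALPHABET:
            if aa == wt_aa:
                continue
            entries.append((pos, aa, float(effect_map.get((pos, aa), 0.0))))

    rng = np.random.default_rng(seed)
    n = len(entries)
    pre_freq = np.full(n, 1.0 / n)
    fitness = np.array([e[2] for e in entries])
    post_freq = pre_freq * np.exp2(fitness)
    post_freq /= post_freq.sum()

    pre_counts = rng.multinomial(depth_pre, pre_freq)
    post_counts = rng.multinomial(depth_post, post_freq)
    return [
        VariantCount(pos, aa, int(cpre), int(cpost))
        for (pos, aa, _), cpre, cpost in zip(entries, pre_counts, post_counts)
    ]
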