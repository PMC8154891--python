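"""Deep-mutational-scanning enrichment scores and NMR peak-list metrics.

Selection screens are summarised by wild-type-normalised log2 enrichment
ratios of variant frequencies between pre- and post-selection sequencing,
and aggregated into per-position conservation scores.  Methyl NMR peak
lists are reduced to chemical-shift deviations (CSD) and bound/free
intensity ratios, with affected probes classified against mean +/- one
standard deviation thresholds.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AA_ALPHABET",
    "VariantCount",
    "EnrichmentScore",
    "MethylPeak",
    "CSDResult",
    "log2_enrichment",
    "position_conservation",
    "csd",
    "classify_affected",
    "read_count_table",
    "write_count_table",
    "read_sparky_peaks",
    "read_peak_csv",
    "scores_to_matrix",
]

#: the 20 amino acids plus the stop codon marker
AA_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY") + ("*",)


@dataclass(frozen=True)
class VariantCount:
    """Sequencing counts for one substitution before and after selection."""

    position: int
    aa: str
    count_pre: float
    count_post: float

    def __post_init__(self):
        if self.aa not in AA_ALPHABET:
            raise ValueError(f"unknown amino acid code {self.aa!r}")
        if self.count_pre < 0 or self.count_post < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class EnrichmentScore:
    position: int
    aa: str
    log2_ratio: float
    is_wildtype: bool
    undefined: bool = False


@dataclass(frozen=True)
class MethylPeak:
    """One methyl resonance: residue, atom, 1H/13C shifts (ppm), intensity."""

    residue: int
    atom: str
    shift_h: float
    shift_c: float
    intensity: float

    def __post_init__(self):
        if not (math.isfinite(self.shift_h) and math.isfinite(self.shift_c)):
            raise ValueError("chemical shifts must be finite")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class CSDResult:
    residue: int
    atom: str
    csd: float
    intensity_ratio: float | None
    affected: bool


def _wildtype_at(wildtype: Mapping[int, str] | str, position: int, offset: int) -> str:
    if isinstance(wildtype, str):
        idx = position - offset
        if not 0 <= idx < len(wildtype):
            raise KeyError(f"position {position} outside the wild-type sequence")
        return wildtype[idx]
    return wildtype[position]


def log2_enrichment(
    counts: Sequence[VariantCount],
    wildtype: Mapping[int, str] | str,
    pseudocount: float = 0.5,
    first_position: int = 1,
) -> list[EnrichmentScore]:
    """Wild-type-normalised log2 enrichment per substitution.

    ``score = log2[(post + pc)/(pre + pc)] - log2[(wt_post + pc)/(wt_pre + pc)]``
    so the wild-type entry at every position scores exactly 0.  ``wildtype``
    is either a sequence string (starting at ``first_position``) or an
    explicit position -> residue map.  With ``pseudocount = 0`` a variant
    absent from one timepoint yields an infinite score flagged ``undefined``.
    """
    by_pos: dict[int, list[VariantCount]] = {}
    for vc in counts:
        by_pos.setdefault(vc.position, []).append(vc)

    wt_ratio: dict[int, float] = {}
    for pos, items in by_pos.items():
        wt_aa = _wildtype_at(wildtype, pos, first_position)
        wt_items = [vc for vc in items if vc.aa == wt_aa]
        if not wt_items:
            raise ValueError(f"no wild-type counts at position {pos} (wt {wt_aa!r})")
        pre = sum(vc.count_pre for vc in wt_items) + pseudocount
        post = sum(vc.count_post for vc in wt_items) + pseudocount
        if pre == 0 or post == 0:
            raise ValueError(f"wild-type counts at position {pos} are zero with zero pseudocount")
        wt_ratio[pos] = post / pre

    scores = []
    for pos, items in sorted(by_pos.items()):
        wt_aa = _wildtype_at(wildtype, pos, first_position)
        for vc in items:
            if vc.aa == wt_aa:
                scores.append(EnrichmentScore(pos, vc.aa, 0.0, True))
                continue
            pre = vc.count_pre + pseudocount
            post = vc.count_post + pseudocount
            if pre == 0 and post == 0:
                scores.append(EnrichmentScore(pos, vc.aa, math.nan, False, undefined=True))
            elif pre == 0:
                scores.append(EnrichmentScore(pos, vc.aa, math.inf, False, undefined=True))
            elif post == 0:
                scores.append(EnrichmentScore(pos, vc.aa, -math.inf, False, undefined=True))
            else:
                scores.append(
                    EnrichmentScore(pos, vc.aa, math.log2(post / pre) - math.log2(wt_ratio[pos]), False)
                )
    return scores


def position_conservation(
    scores: Iterable[EnrichmentScore], method: str = "mean"
) -> dict[int, float]:
    """Aggregate substitution scores into one conservation value per position.

    Aggregates over non-wild-type, non-stop substitutions; strongly negative
    values mark positions conserved for function.  ``method`` is ``mean``
    (default), ``median`` or ``min``.
    """
    agg = {"mean": np.mean, "median": np.median, "min": np.min}
    if method not in agg:
        raise ValueError(f"unknown aggregation {method!r}")
    by_pos: dict[int, list[float]] = {}
    for s in scores:
        if s.is_wildtype or s.aa == "*" or s.undefined:
            continue
        by_pos.setdefault(s.position, []).append(s.log2_ratio)
    out = {}
    for pos, values in sorted(by_pos.items()):
        if not values:
            raise ValueError(f"no usable substitution scores at position {pos}")
        out[pos] = float(agg[method](values))
    return out


def csd(peak_free: MethylPeak, peak_bound: MethylPeak) -> float:
    """Combined methyl chemical-shift deviation (ppm).

    ``csd = sqrt(0.5 * (dH^2 + dC^2 / 4))`` where dH/dC are the 1H/13C shift
    differences; the carbon term is scaled down by its wider ppm range.
    """
    if (peak_free.residue, peak_free.atom) != (peak_bound.residue, peak_bound.atom):
        raise ValueError(
            f"peak identity mismatch: {peak_free.residue}{peak_free.atom} vs "
            f"{peak_bound.residue}{peak_bound.atom}"
        )
    dh = peak_bound.shift_h - peak_free.shift_h
    dc = peak_bound.shift_c - peak_free.shift_c
    return math.sqrt(0.5 * (dh**2 + dc**2 / 4))


def classify_affected(
    csds: Sequence[float | None],
    intensity_ratios: Sequence[float | None] | None = None,
) -> list[bool]:
    """Flag probes perturbed by complex formation.

    A probe is affected when its CSD exceeds mean + 1 sd of all CSDs, or its
    bound/free intensity ratio falls below mean - 1 sd of all ratios
    (population sd).  ``None`` entries mark probes broadened beyond
    detection, which are affected by convention and excluded from the
    threshold statistics.
    """
    n = len(csds)
    if intensity_ratios is None:
        intensity_ratios = [None] * n
    if len(intensity_ratios) != n:
        raise ValueError("csds and intensity_ratios must be aligned")
    obs_csd = np.array([c for c in csds if c is not None], float)
    if obs_csd.size < 3:
        raise ValueError("need at least 3 observed probes to define thresholds")
    csd_thresh = obs_csd.mean() + obs_csd.std()  # population sd
    obs_ratio = np.array([r for r in intensity_ratios if r is not None], float)
    ratio_thresh = obs_ratio.mean() - obs_ratio.std() if obs_ratio.size >= 3 else None

    flags = []
    for c, r in zip(csds, intensity_ratios):
        if c is None:
            flags.append(True)  # broadened beyond detection
            continue
        hit = c > csd_thresh
        if ratio_thresh is not None and r is not None:
            hit = hit or r < ratio_thresh
        flags.append(bool(hit))
    return flags


# ---------------------------------------------------------------------------
# I/O


def read_count_table(path) -> list[VariantCount]:
    """TSV with columns position, aa, count_pre, count_post."""
    df = pd.read_csv(path, sep="\t")
    return [
        VariantCount(int(r.position), str(r.aa), float(r.count_pre), float(r.count_post))
        for r in df.itertuples()
    ]


def write_count_table(counts: Sequence[VariantCount], path) -> None:
    pd.DataFrame(
        {
            "position": [c.position for c in counts],
            "aa": [c.aa for c in counts],
            "count_pre": [c.count_pre for c in counts],
            "count_post": [c.count_post for c in counts],
        }
    ).to_csv(path, sep="\t", index=False)


_SPARKY_ASSIGNMENT = re.compile(r"^([A-Za-z])(\d+)([A-Za-z0-9']+)-?.*$")


def read_sparky_peaks(path) -> list[MethylPeak]:
    """Whitespace-delimited peak list: assignment, w1 (13C), w2 (1H), height.

    Assignments look like ``L81CD2-HD2`` or ``V152CG1``; the residue number
    and the methyl atom token are extracted from the first axis label.
    """
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            parts = line.split()
            if len(parts) < 3:
                continue
            m = _SPARKY_ASSIGNMENT.match(parts[0])
            if not m:
                raise ValueError(f"cannot parse assignment {parts[0]!r}")
            _, residue, atom = m.groups()
            w1, w2 = float(parts[1]), float(parts[2])
            height = float(parts[3]) if len(parts) > 3 else 0.0
            peaks.append(MethylPeak(int(residue), atom, shift_h=w2, shift_c=w1, intensity=height))
    return peaks


def read_peak_csv(path) -> list[MethylPeak]:
    """Tidy CSV dialect: residue, atom, shift_h_ppm, shift_c_ppm, intensity."""
    df = pd.read_csv(path)
    return [
        MethylPeak(int(r.residue), str(r.atom), float(r.shift_h_ppm), float(r.shift_c_ppm), float(r.intensity))
        for r in df.itertuples()
    ]


def scores_to_matrix(scores: Iterable[EnrichmentScore]) -> pd.DataFrame:
    """Positions x 21 matrix of log2 ratios (heatmap export, TSV-friendly)."""
    rows: dict[int, dict[str, float]] = {}
    for s in scores:
        rows.setdefault(s.position, {})[s.aa] = s.log2_ratio
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return df.reindex(columns=list(AA_ALPHABET))
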