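"""Efficiency-of-plaquing statistics and host-range cross-tabulation.

Titres are estimated from plaque counts with exact Poisson confidence
intervals; zero-count conditions are censored at the plated-volume
detection limit rather than given a pseudo-count, so "unable to produce
plaques" propagates as a bound.  Calcium dependence is called at a
configurable log-reduction threshold (default 4 log), and antibody
neutralisation is tiered against water/pre-bleed controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

CONDITIONS = ("Ca_10mM", "EDTA_0.1mM", "antibody", "pre_bleed", "water")
CWPS_TYPES = ("A", "B", "C", "U")

DEPENDENT_LOG_THRESHOLD = 4.0


@dataclass(frozen=True)
class PlaqueAssay:
    phage_id: str
    condition: str
    plaque_count: int
    volume_plated_ml: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.plaque_count < 0:
            raise ValueError("plaque_count must be >= 0")
        if self.volume_plated_ml <= 0:
            raise ValueError("volume_plated_ml must be > 0")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class TitreResult:
    """Estimated titre in pfu/ml; censored results carry an upper bound."""

    phage_id: str
    condition: str
    pfu_per_ml: float | None
    ci_low: float | None
    ci_high: float | None
    censored: bool
    detection_limit: float
    total_count: int
    total_volume_ml: float


def titre(assays: Sequence[PlaqueAssay], *, allow_mixed_volumes: bool = False,
          confidence: float = 0.95) -> TitreResult:
    """Titre with an exact (Garwood) Poisson CI on the summed counts.

    All replicates must share one phage and condition.  Zero total count
    yields a censored result with upper bound 1 / total plated volume.
    """
    if not assays:
        raise ValueError("at least one replicate required")
    phages = {a.phage_id for a in assays}
    conditions = {a.condition for a in assays}
    if len(phages) != 1 or len(conditions) != 1:
        raise ValueError("titre() expects one phage and one condition")
    volumes = {a.volume_plated_ml for a in assays}
    if len(volumes) > 1 and not allow_mixed_volumes:
        raise ValueError("mixed plated volumes; pass allow_mixed_volumes=True")
    total = sum(a.plaque_count for a in assays)
    total_volume = sum(a.volume_plated_ml for a in assays)
    limit = 1.0 / total_volume
    if total == 0:
        return TitreResult(
            phage_id=phages.pop(), condition=conditions.pop(),
            pfu_per_ml=None, ci_low=None, ci_high=None,
            censored=True, detection_limit=limit,
            total_count=0, total_volume_ml=total_volume,
        )
    alpha = 1.0 - confidence
    lo = stats.chi2.ppf(alpha / 2.0, 2 * total) / 2.0
    hi = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * (total + 1)) / 2.0
    return TitreResult(
        phage_id=phages.pop(), condition=conditions.pop(),
        pfu_per_ml=total / total_volume,
        ci_low=lo / total_volume, ci_high=hi / total_volume,
        censored=False, detection_limit=limit,
        total_count=total, total_volume_ml=total_volume,
    )


@dataclass(frozen=True)
class EopResult:
    phage_id: str
    eop: float | None
    eop_upper_bound: float | None
    log10_reduction: float | None
    reduction_is_lower_bound: bool
    category: str  # independent | dependent | no_plaques
    flags: tuple[str, ...] = ()


def compute_eop(
    titre_test: TitreResult,
    titre_reference: TitreResult,
    *,
    dependent_log_threshold: float = DEPENDENT_LOG_THRESHOLD,
) -> EopResult:
    """EOP = test titre / reference titre, with censoring-aware bounds.

    A censored test titre gives a ">= bound" log reduction and category
    ``no_plaques``; an uncensored reduction of at least
    ``dependent_log_threshold`` logs is ``dependent``, anything less is
    ``independent``.  A censored reference is an error.
    """
    if titre_reference.censored or not titre_reference.pfu_per_ml:
        raise ValueError("reference titre is censored or zero")
    ref = titre_reference.pfu_per_ml
    flags: list[str] = []
    if titre_test.censored:
        bound = titre_test.detection_limit / ref
        reduction_bound = -math.log10(bound)
        if reduction_bound < dependent_log_threshold:
            flags.append("bound_below_threshold")
        return EopResult(
            phage_id=titre_test.phage_id,
            eop=None, eop_upper_bound=bound,
            log10_reduction=reduction_bound,
            reduction_is_lower_bound=True,
            category="no_plaques",
            flags=tuple(flags),
        )
    eop = titre_test.pfu_per_ml / ref
    if eop > 1.0:
        flags.append("eop_above_one")
    reduction = -math.log10(eop)
    category = "dependent" if reduction >= dependent_log_threshold else "independent"
    return EopResult(
        phage_id=titre_test.phage_id,
        eop=eop, eop_upper_bound=None,
        log10_reduction=reduction,
        reduction_is_lower_bound=False,
        category=category,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class NeutralizationResult:
    phage_id: str
    eop: EopResult
    tier: str  # not_neutralized | weak | partial | strong
    non_specific: bool
    flags: tuple[str, ...] = ()


def neutralization(
    titre_with_antibody: TitreResult,
    titre_water_control: TitreResult,
    titre_pre_bleed: TitreResult | None = None,
    *,
    strong_log: float = 4.0,
    partial_log: float = 2.0,
    none_log: float = 1.0,
    pre_bleed_tolerance_log: float = 0.5,
) -> NeutralizationResult:
    """Tiered antibody-neutralisation call against the water control.

    Tiers: strong (>= 4 log), partial (>= 2 log), weak (>= 1 log),
    not_neutralized (< 1 log).  A pre-bleed control deviating from the
    water control by more than 0.5 log flags the result non-specific.
    """
    if titre_water_control is None:
        raise ValueError("water control is required")
    eop = compute_eop(titre_with_antibody, titre_water_control,
                      dependent_log_threshold=strong_log)
    reduction = eop.log10_reduction if eop.log10_reduction is not None else 0.0
    if reduction >= strong_log:
        tier = "strong"
    elif reduction >= partial_log:
        tier = "partial"
    elif reduction >= none_log:
        tier = "weak"
    else:
        tier = "not_neutralized"
    non_specific = False
    flags: list[str] = []
    if titre_pre_bleed is not None:
        pre = compute_eop(titre_pre_bleed, titre_water_control,
                          dependent_log_threshold=strong_log)
        pre_reduction = abs(pre.log10_reduction or 0.0)
        if pre_reduction > pre_bleed_tolerance_log:
            non_specific = True
            flags.append("pre_bleed_reduction")
    return NeutralizationResult(
        phage_id=titre_with_antibody.phage_id,
        eop=eop, tier=tier, non_specific=non_specific, flags=tuple(flags),
    )


@dataclass
class HostRangeMatrix:
    """Boolean phage x strain infection matrix with per-strain CWPS types."""

    phages: list[str]
    strains: list[str]
    matrix: np.ndarray
    strain_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (len(self.phages), len(self.strains)):
            raise ValueError("matrix shape does not match phage/strain lists")
        for strain in self.strains:
            t = self.strain_types.get(strain)
            if t not in CWPS_TYPES:
                raise ValueError(f"strain {strain!r}: unknown CWPS type {t!r}")


@dataclass(frozen=True)
class CrossTab:
    strains_infected_by_type: dict[str, int]
    phages_infecting_type: dict[str, int]


def crosstab(matrix: HostRangeMatrix) -> CrossTab:
    """Counts of infected strains and infecting phages per CWPS type."""
    strains_by_type = {t: 0 for t in CWPS_TYPES}
    phages_by_type = {t: 0 for t in CWPS_TYPES}
    cols_by_type: dict[str, list[int]] = {t: [] for t in CWPS_TYPES}
    for j, strain in enumerate(matrix.strains):
        cols_by_type[matrix.strain_types[strain]].append(j)
    for t, cols in cols_by_type.items():
        if not cols:
            continue
        sub = matrix.matrix[:, cols]
        strains_by_type[t] = int(np.count_nonzero(sub.any(axis=0)))
        phages_by_type[t] = int(np.count_nonzero(sub.any(axis=1)))
    return CrossTab(
        strains_infected_by_type=strains_by_type,
        phages_infecting_type=phages_by_type,
    )


def read_plaque_tsv(path: str | Path) -> list[PlaqueAssay]:
    """TSV columns: phage, condition, count, volume_ml, replicate."""
    assays: list[PlaqueAssay] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("phage"):
                continue
            phage, condition, count, volume, replicate = line.split("\t")[:5]
            assays.append(
                PlaqueAssay(phage, condition, int(count), float(volume),
                            int(replicate))
            )
    return assays


def write_plaque_tsv(assays: Iterable[PlaqueAssay], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("phage\tcondition\tcount\tvolume_ml\treplicate\n")
        for a in assays:
            fh.write(
                f"{a.phage_id}\t{a.condition}\t{a.plaque_count}\t"
                f"{a.volume_plated_ml:g}\t{a.replicate}\n"
            )


def read_host_range(matrix_path: str | Path,
                    types_path: str | Path) -> HostRangeMatrix:
    """Read a 0/1 phage x strain matrix TSV and a strain-type sidecar TSV."""
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        strains = header[1:]
        phages: list[str] = []
        rows: list[list[bool]] = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            phages.append(parts[0])
            if len(parts) - 1 != len(strains):
                raise ValueError(f"row {parts[0]!r}: wrong number of cells")
            rows.append([bool(int(v)) for v in parts[1:]])
    strain_types: dict[str, str] = {}
    with open(types_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("strain"):
                continue
            strain, cwps = line.split("\t")[:2]
            strain_types[strain] = cwps
    return HostRangeMatrix(
        phages=phages, strains=strains,
        matrix=np.array(rows, dtype=bool), strain_types=strain_types,
    )


def write_host_range(matrix: HostRangeMatrix, matrix_path: str | Path,
                     types_path: str | Path) -> None:
    with open(matrix_path, "w") as fh:
        fh.write("phage\t" + "\t".join(matrix.strains) + "\n")
        for i, phage in enumerate(matrix.phages):
            cells = "\t".join(str(int(v)) for v in matrix.matrix[i])
            fh.write(f"{phage}\t{cells}\n")
    with open(types_path, "w") as fh:
        fh.write("strain\tcwps_type\n")
        for strain in matrix.strains:
            fh.write(f"{strain}\t{matrix.strain_types[strain]}\n")


def eop_table(results: Mapping[str, EopResult]) -> list[dict[str, object]]:
    rows = []
    for phage_id in sorted(results):
        r = results[phage_id]
        rows.append(
            {
                "phage_id": phage_id,
                "eop": r.eop if r.eop is not None else f"<{r.eop_upper_bound:.3g}",
                "log10_reduction": (
                    f">={r.log10_reduction:.2f}" if r.reduction_is_lower_bound
                    else f"{r.log10_reduction:.2f}"
                ),
                "category": r.category,
                "flags": ";".join(r.flags),
            }
        )
    return rows
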