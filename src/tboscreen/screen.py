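"""Per-drug effect estimation, significance and ranking for organoid screens.

Every treated group is summarized relative to the plate's vehicle (DMSO)
control: the *normalized effect* is the ratio of group means of a chosen
per-organoid measurement (tumor compartment: summed tumor brightness in
tumor areas or tumor area; microenvironment: neuronal summed brightness or
TME area). Group differences are tested with the two-sided Wilcoxon
rank-sum test (exact null distribution for small samples without ties,
normal approximation with tie correction otherwise), and p-values are
Benjamini-Hochberg adjusted across drugs within each compartment.

A drug is called a hit when its adjusted tumor p-value is below alpha and
its normalized tumor effect is below 1 (a reduction). Selectivity — the
normalized microenvironment effect minus the normalized tumor effect — is
positive for drugs that are more toxic to tumor than to healthy tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import aggregate_group
from .types import OrganoidMeasurement

#: measurement fields usable as compartment readouts
TUMOR_FIELDS = ("tumor_sum", "tumor_area")
TME_FIELDS = ("neuronal_sum", "tme_area")


@dataclass
class TreatmentGroup:
    """One drug/dose group of organoid measurements."""

    drug: str
    measurements: list[OrganoidMeasurement]
    dose: float | None = None
    role: str = "treated"  # "treated" | "control"

    def __post_init__(self) -> None:
        if len(self.measurements) < 1:
            raise ValueError(f"group {self.drug!r} has no measurements")
        if self.role not in ("treated", "control"):
            raise ValueError(f"invalid role {self.role!r}")

    def values(self, fieldname: str) -> np.ndarray:
        return np.array([getattr(m, fieldname) for m in self.measurements], dtype=float)

    @property
    def n(self) -> int:
        return len(self.measurements)


def groups_from_measurements(
    measurements: pd.DataFrame, layout: pd.DataFrame
) -> list[TreatmentGroup]:
    """Assemble treatment groups from a measurements table and plate layout.

    ``measurements`` has one row per well (columns as written by the
    quantification stage), ``layout`` maps well_id to drug/dose/role.
    """
    merged = measurements.merge(layout, on="well_id", validate="one_to_one")
    groups = []
    for (drug, dose, role), sub in merged.groupby(["drug", "dose", "role"], dropna=False, sort=False):
        ms = [
            OrganoidMeasurement(
                tumor_sum=r.tumor_sum,
                neuronal_sum=r.neuronal_sum,
                tumor_area=int(r.tumor_area),
                tme_area=int(r.tme_area),
                well_id=r.well_id,
            )
            for r in sub.itertuples()
        ]
        groups.append(
            TreatmentGroup(drug=drug, measurements=ms, dose=None if pd.isna(dose) else dose, role=role)
        )
    return groups


def normalize_to_control(
    treated: TreatmentGroup, control: TreatmentGroup, fieldname: str
) -> tuple[float, float]:
    """Normalized effect (ratio of group means) and its SEM.

    The SEM is the treated group's SEM divided by the control mean; the
    control group's own uncertainty is not propagated (the control mean is
    treated as the plate's fixed reference level).
    """
    ctrl = aggregate_group(control.measurements, fieldname)
    if ctrl.mean <= 0:
        raise ValueError(
            f"control mean of {fieldname} is {ctrl.mean:g}; cannot normalize"
        )
    trt = aggregate_group(treated.measurements, fieldname)
    return trt.mean / ctrl.mean, trt.sem / ctrl.mean


def test_group_difference(
    treated_values: Sequence[float], control_values: Sequence[float]
) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum p-value for treated vs control.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties; otherwise the normal approximation with
    tie correction. Two groups with all values identical are maximally
    compatible with the null and return p = 1. Returns (p, method).
    """
    x = np.asarray(treated_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0, "degenerate"
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= 20 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.pvalue), "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue), "asymptotic"


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")


@dataclass
class ScreenResult:
    """Ranked per-drug screen summary plus the analysis settings used."""

    table: pd.DataFrame
    alpha: float
    tumor_field: str
    tme_field: str
    control_drug: str
    settings: dict = field(default_factory=dict)

    @property
    def hits(self) -> pd.DataFrame:
        return self.table[self.table["hit"]]

    @property
    def n_hits(self) -> int:
        return int(self.table["hit"].sum())


def score_screen(
    groups: Sequence[TreatmentGroup],
    alpha: float = 0.05,
    tumor_field: str = "tumor_area",
    tme_field: str = "tme_area",
    strongest_last: bool = True,
) -> ScreenResult:
    """Score a whole screen against its control group.

    Per drug: normalized tumor and TME effects with SEMs, raw Wilcoxon
    p-values vs control, BH-adjusted p-values (across drugs, per
    compartment), hit flag (adjusted tumor p < alpha and tumor effect < 1)
    and selectivity. The table is ordered by anti-tumor effect; with
    ``strongest_last`` (the figure convention) the strongest tumor
    reduction sorts last.
    """
    controls = [g for g in groups if g.role == "control"]
    if len(controls) != 1:
        raise ValueError(f"exactly one control group required, found {len(controls)}")
    control = controls[0]
    treated = [g for g in groups if g.role != "control"]
    if not treated:
        raise ValueError("no treated groups to score")

    rows = []
    for g in treated:
        eff_t, sem_t = normalize_to_control(g, control, tumor_field)
        eff_m, sem_m = normalize_to_control(g, control, tme_field)
        p_t, method = test_group_difference(g.values(tumor_field), control.values(tumor_field))
        p_m, _ = test_group_difference(g.values(tme_field), control.values(tme_field))
        rows.append(
            {
                "drug": g.drug,
                "n": g.n,
                "tumor_effect": eff_t,
                "tumor_sem": sem_t,
                "tme_effect": eff_m,
                "tme_sem": sem_m,
                "p_tumor": p_t,
                "p_tme": p_m,
                "test_method": method,
                "selectivity": eff_m - eff_t,
            }
        )
    table = pd.DataFrame(rows)
    table["q_tumor"] = bh_adjust(table["p_tumor"])
    table["q_tme"] = bh_adjust(table["p_tme"])
    table["hit"] = (table["q_tumor"] < alpha) & (table["tumor_effect"] < 1.0)
    table = table.sort_values(
        "tumor_effect", ascending=not strongest_last, kind="mergesort"
    ).reset_index(drop=True)
    return ScreenResult(
        table=table,
        alpha=alpha,
        tumor_field=tumor_field,
        tme_field=tme_field,
        control_drug=control.drug,
        settings={"n_control": control.n, "multiple_testing": "benjamini-hochberg"},
    )
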