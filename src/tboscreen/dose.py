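"""Dose-response curves and the therapeutic window.

For each tested concentration the tumor and neuronal compartments are
normalized to the vehicle control (dose 0) and compared to it with the
two-sided Wilcoxon rank-sum test. The curve logic is deliberately
nonparametric: the *first significant dose* of a compartment is the lowest
dose with a significant reduction, and the therapeutic window is the dose
range that is on-target but not yet neurotoxic:

* lower bound — first significant tumor dose;
* upper bound — the largest tested dose strictly below the first
  significant neuronal dose (or the maximum tested dose when the neuronal
  compartment never responds);
* the window exists when both are defined and lower <= upper.

An optional Hill fit reports EC50s but never gates the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .screen import TreatmentGroup, bh_adjust, normalize_to_control, test_group_difference

COMPARTMENTS = ("tumor", "neuronal")
#: default per-compartment measurement fields (summed brightness, as in the
#: dose-response readout: tumor marker in tumor areas, neuronal marker in
#: the whole organoid)
DEFAULT_FIELDS = {"tumor": "tumor_sum", "neuronal": "neuronal_sum"}


@dataclass
class DoseResponseCurve:
    """Long-format per-dose, per-compartment summary of one drug.

    ``table`` columns: drug, dose, compartment, mean (normalized), sem, n,
    p (vs control; NaN for the dose-0 control row, whose mean is 1 by
    construction).
    """

    drug: str
    table: pd.DataFrame
    fields: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_FIELDS))

    @property
    def doses(self) -> np.ndarray:
        return np.unique(self.table["dose"].to_numpy())

    def compartment(self, name: str) -> pd.DataFrame:
        if name not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {name!r}; expected one of {COMPARTMENTS}")
        sub = self.table[self.table["compartment"] == name]
        return sub.sort_values("dose").reset_index(drop=True)


@dataclass(frozen=True)
class TherapeuticWindow:
    """Safe-yet-efficacious dose interval derived from a curve."""

    lower: float | None
    upper: float | None
    exists: bool
    alpha: float


def build_curve(
    dose_groups: Sequence[TreatmentGroup],
    control: TreatmentGroup,
    fields: Mapping[str, str] | None = None,
    adjust: bool = False,
) -> DoseResponseCurve:
    """Build a dose-response curve from per-dose groups and a dose-0 control.

    Requires at least two distinct nonzero doses, strictly one group per
    dose. Normalized means/SEMs come from the screen-normalization rules;
    each dose is tested against the control per compartment. Per-dose tests
    are unadjusted by default (mirroring per-dose significance reporting);
    ``adjust=True`` applies Benjamini-Hochberg within each compartment.
    """
    fields = dict(fields or DEFAULT_FIELDS)
    doses = [g.dose for g in dose_groups]
    if any(d is None or d <= 0 for d in doses):
        raise ValueError("every treated group needs a positive dose")
    if len(set(doses)) != len(doses):
        raise ValueError(f"duplicate doses in curve: {sorted(doses)}")
    if len(doses) < 2:
        raise ValueError("need at least two nonzero doses")
    drugs = {g.drug for g in dose_groups}
    if len(drugs) != 1:
        raise ValueError(f"dose groups must belong to one drug, got {sorted(drugs)}")
    (drug,) = drugs

    rows = []
    for comp in COMPARTMENTS:
        fieldname = fields[comp]
        ctrl_n = control.n
        rows.append(
            {"drug": drug, "dose": 0.0, "compartment": comp, "mean": 1.0,
             "sem": 0.0, "n": ctrl_n, "p": np.nan}
        )
        for g in sorted(dose_groups, key=lambda g: g.dose):
            eff, sem = normalize_to_control(g, control, fieldname)
            p, _ = test_group_difference(g.values(fieldname), control.values(fieldname))
            rows.append(
                {"drug": drug, "dose": float(g.dose), "compartment": comp,
                 "mean": eff, "sem": sem, "n": g.n, "p": p}
            )
    table = pd.DataFrame(rows)
    if adjust:
        for comp in COMPARTMENTS:
            sel = (table["compartment"] == comp) & table["p"].notna()
            table.loc[sel, "p"] = bh_adjust(table.loc[sel, "p"])
    return DoseResponseCurve(drug=drug, table=table, fields=fields)


def first_significant_dose(
    curve: DoseResponseCurve, compartment: str, alpha: float = 0.05
) -> float | None:
    """Lowest dose with a significant *reduction* (p < alpha and mean < 1).

    Returns None when no dose qualifies.
    """
    sub = curve.compartment(compartment)
    sig = sub[(sub["p"] < alpha) & (sub["mean"] < 1.0)]
    if sig.empty:
        return None
    return float(sig["dose"].min())


def therapeutic_window(curve: DoseResponseCurve, alpha: float = 0.05) -> TherapeuticWindow:
    """Derive the therapeutic window of a two-compartment curve."""
    lower = first_significant_dose(curve, "tumor", alpha)
    neuronal_onset = first_significant_dose(curve, "neuronal", alpha)
    tested = np.sort(curve.doses[curve.doses > 0])
    if neuronal_onset is None:
        upper: float | None = float(tested[-1])
    else:
        below = tested[tested < neuronal_onset]
        upper = float(below[-1]) if below.size else None
    exists = lower is not None and upper is not None and lower <= upper
    return TherapeuticWindow(lower=lower, upper=upper, exists=exists, alpha=alpha)


def _hill(dose, bottom, ec50, hill):
    return 1.0 - (1.0 - bottom) * dose**hill / (ec50**hill + dose**hill)


def fit_hill(curve: DoseResponseCurve, compartment: str) -> dict[str, float]:
    """Optional descriptive Hill fit of normalized response vs dose.

    Fits ``1 - (1 - bottom) * d^h / (EC50^h + d^h)`` to the per-dose
    normalized means (top pinned at 1, the control level). Reporting aid
    only; never used by the window logic. Returns bottom, ec50, hill.
    """
    sub = curve.compartment(compartment)
    d = sub["dose"].to_numpy(dtype=float)
    m = sub["mean"].to_numpy(dtype=float)
    pos = d > 0
    if pos.sum() < 3:
        raise ValueError("Hill fit needs at least three nonzero doses")
    p0 = (max(float(m[pos].min()), 1e-3), float(np.median(d[pos])), 1.5)
    bounds = ([0.0, d[pos].min() / 100.0, 0.2], [1.0, d[pos].max() * 100.0, 10.0])
    popt, _ = curve_fit(_hill, d[pos], m[pos], p0=p0, bounds=bounds, maxfev=20000)
    return {"bottom": float(popt[0]), "ec50": float(popt[1]), "hill": float(popt[2])}
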