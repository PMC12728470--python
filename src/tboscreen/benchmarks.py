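"""Parameter-recovery benchmarks for the whole pipeline.

Every function simulates a study with the synthetic generators, runs the
relevant pipeline stage, and reports how well known ground truth is
recovered. They double as the package's self-validation campaign: the test
suite asserts on their outputs and ``scripts/acceptance.py`` records them.

Simulation sizes are chosen so the full campaign runs in a few minutes on
one CPU: single-organoid accuracy checks use the default phantom (29
planes, 96 x 96), while the large repeated-simulation campaigns (type-I
error, power, window recovery) use the reduced :data:`SMALL_PHANTOM`
geometry with identical intensities, tumor fraction and noise.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import dose as dose_mod
from . import quantify, screen, states
from .synthetic import (
    SMALL_PHANTOM,
    DrugTruth,
    PhantomSpec,
    ScreenTruthTable,
    SyntheticCellSpec,
    derive_seed,
    dose_truth_table,
    generate_expression_matrix,
    generate_organoid_stack,
    generate_screen_dataset,
    screen_layout,
)
from .synthetic.counts import default_signatures
from .types import NEURONAL, TUMOR, ImageStack


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0


# ------------------------------------------------------------------ imaging

def sum_brightness_oracle_error(n_stacks: int = 50, seed: int = 0) -> float:
    """Max relative deviation of sum_brightness from a naive voxel loop.

    Random stacks and random masks; the oracle walks every voxel in Python.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_stacks):
        shape = (int(rng.integers(3, 7)), int(rng.integers(8, 20)), int(rng.integers(8, 20)))
        stack = ImageStack(rng.uniform(0, 500, size=shape + (2,)))
        mask = rng.random(shape) > rng.uniform(0.2, 0.8)
        for channel in (TUMOR, NEURONAL):
            _, total = quantify.sum_brightness(stack, mask, channel)
            oracle = 0.0
            ch = stack.channel(channel)
            for z in range(shape[0]):
                for y in range(shape[1]):
                    for x in range(shape[2]):
                        if mask[z, y, x]:
                            oracle += float(ch[z, y, x])
            denom = max(abs(oracle), 1.0)
            worst = max(worst, abs(total - oracle) / denom)
    return worst


def segmentation_recovery(
    n_noiseless: int = 5, n_noisy: int = 20, noise_fraction: float = 0.05, seed: int = 0
) -> dict[str, float]:
    """Mask agreement with voxel truth on default-size phantoms.

    Noiseless phantoms must be segmented exactly; with additive noise at
    ``noise_fraction`` of the tumor-marker intensity the voxel-wise Jaccard
    is reported as a minimum over phantoms (organoid and tumor masks).
    """
    base = PhantomSpec()
    noiseless_min = 1.0
    for i in range(n_noiseless):
        spec = replace(base, noise_sd=0.0, seed=derive_seed(seed, "seg0", i))
        stack, truth = generate_organoid_stack(spec)
        seg = quantify.segment(stack)
        noiseless_min = min(
            noiseless_min,
            _jaccard(seg.organoid_mask, truth.organoid_mask),
            _jaccard(seg.tumor_mask, truth.tumor_mask),
        )
    noisy_min = 1.0
    for i in range(n_noisy):
        spec = replace(
            base,
            noise_sd=noise_fraction * base.tumor_intensity,
            seed=derive_seed(seed, "segN", i),
        )
        stack, truth = generate_organoid_stack(spec)
        seg = quantify.segment(stack)
        noisy_min = min(
            noisy_min,
            _jaccard(seg.organoid_mask, truth.organoid_mask),
            _jaccard(seg.tumor_mask, truth.tumor_mask),
        )
    return {"noiseless_min_jaccard": noiseless_min, "noisy_min_jaccard": noisy_min}


# ------------------------------------------------------------------- screen

def _screen_result(truth: ScreenTruthTable, spec: PhantomSpec, background="compartment"):
    ms = quantify.measure_stacks(
        ((w, s) for w, s, _ in generate_screen_dataset(truth, spec)),
        background=background,
    )
    groups = screen.groups_from_measurements(
        pd.DataFrame([m.as_row() for m in ms]), screen_layout(truth)
    )
    return screen.score_screen(groups, tumor_field="tumor_sum", tme_field="neuronal_sum")


def effect_recovery(n_per_group: int = 8, seed: int = 0) -> dict[str, float]:
    """Normalized-effect recovery for a 12-drug screen.

    Kill fractions k_T in {0, 0.25, 0.5, 0.75}, three drugs each; k_N cycles
    through the same values on the neuronal channel. Background subtraction
    on. Reports the worst absolute error of the normalized tumor effect vs
    1 - k_T (and the neuronal analogue) over all drugs.
    """
    kts = [0.0, 0.25, 0.5, 0.75] * 3
    kns = [0.25, 0.5, 0.75, 0.0] * 3
    drugs = [DrugTruth("DMSO", control=True, n_organoids=n_per_group)] + [
        DrugTruth(f"drug{i:02d}", k_T=kt, k_N=kn, n_organoids=n_per_group)
        for i, (kt, kn) in enumerate(zip(kts, kns))
    ]
    spec = PhantomSpec(seed=seed)
    result = _screen_result(ScreenTruthTable(drugs), spec)
    table = result.table.set_index("drug")
    err_t = max(
        abs(table.loc[f"drug{i:02d}", "tumor_effect"] - (1 - kt))
        for i, kt in enumerate(kts)
    )
    err_n = max(
        abs(table.loc[f"drug{i:02d}", "tme_effect"] - (1 - kn))
        for i, kn in enumerate(kns)
    )
    return {"tumor_max_abs_error": float(err_t), "neuronal_max_abs_error": float(err_n)}


def _null_group_values(spec: PhantomSpec, n: int, seed_parts) -> np.ndarray:
    values = []
    for j in range(n):
        s = replace(spec, seed=derive_seed(*seed_parts, j))
        stack, _ = generate_organoid_stack(s)
        seg = quantify.segment(stack)
        m = quantify.measure_organoid(stack, seg, background="compartment")
        values.append(m.tumor_sum)
    return np.array(values)


def type_i_error_rate(n_drugs: int = 1000, n_per_group: int = 4, alpha: float = 0.05,
                      seed: int = 0) -> float:
    """Fraction of null drugs (k_T = k_N = 0) rejected at ``alpha``.

    Each pseudo-drug gets its own treated and control groups of
    ``n_per_group`` phantoms; the exact rank-sum test is used throughout.
    Uses the reduced phantom geometry.
    """
    rejections = 0
    for i in range(n_drugs):
        treated = _null_group_values(SMALL_PHANTOM, n_per_group, (seed, "t1", i))
        control = _null_group_values(SMALL_PHANTOM, n_per_group, (seed, "c1", i))
        p, _ = screen.test_group_difference(treated, control)
        rejections += p < alpha
    return rejections / n_drugs


def detection_power(k_T: float = 0.5, n_sim: int = 200, n_per_group: int = 4,
                    alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of simulations detecting a k_T kill at ``alpha`` (raw p)."""
    detected = 0
    spec_treated = SMALL_PHANTOM.with_treatment(k_T, 0.0)
    for i in range(n_sim):
        treated = _null_group_values(spec_treated, n_per_group, (seed, "tp", i))
        control = _null_group_values(SMALL_PHANTOM, n_per_group, (seed, "cp", i))
        p, _ = screen.test_group_difference(treated, control)
        detected += p < alpha
    return detected / n_sim


# ------------------------------------------------------------ dose response

#: six-dose ground truth: tumor response from dose 2, neuronal from dose 5
WINDOW_DOSES = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
WINDOW_K_T = (0.0, 0.4, 0.6, 0.8, 0.9, 0.95)
WINDOW_K_N = (0.0, 0.0, 0.0, 0.0, 0.4, 0.6)
#: per-dose alpha for window calling; with the phantom's measurement noise
#: true onsets test at p ~ 1e-4, so a strict alpha suppresses false onsets
#: at the unaffected doses without costing sensitivity
WINDOW_ALPHA = 0.01


def window_recovery_rate(n_sim: int = 100, n_per_dose: int = 8, seed: int = 0) -> float:
    """Fraction of simulated dose courses recovering the true window [2, 4]."""
    hits = 0
    for i in range(n_sim):
        truth = dose_truth_table(
            "drugX", WINDOW_DOSES, WINDOW_K_T, WINDOW_K_N, n_organoids=n_per_dose
        )
        spec = replace(SMALL_PHANTOM, seed=derive_seed(seed, "win", i))
        ms = quantify.measure_stacks(
            ((w, s) for w, s, _ in generate_screen_dataset(truth, spec)),
            background="compartment",
        )
        groups = screen.groups_from_measurements(
            pd.DataFrame([m.as_row() for m in ms]), screen_layout(truth)
        )
        control = next(g for g in groups if g.role == "control")
        treated = [g for g in groups if g.role != "control"]
        curve = dose_mod.build_curve(treated, control)
        window = dose_mod.therapeutic_window(curve, alpha=WINDOW_ALPHA)
        hits += window.exists and (window.lower, window.upper) == (2.0, 4.0)
    return hits / n_sim


# --------------------------------------------------------------- cell states

def cellstate_recovery(seed: int = 0) -> dict[str, float]:
    """Label accuracy and proportion/cycling recovery on the default design."""
    spec = SyntheticCellSpec(seed=derive_seed(seed, "cells"))
    counts, truth = generate_expression_matrix(spec)
    norm = states.normalize_log(states.matrix_to_anndata(counts, truth["condition"]))
    sigs = states.SignatureSet.from_dict(spec.signature_genes)
    assignment = states.classify(norm, sigs, seed=derive_seed(seed, "score"))
    accuracy = float((assignment.labels.to_numpy() == truth["state"].to_numpy()).mean())
    props = states.state_proportions(assignment.labels, norm.obs["condition"])
    cyc = states.cycling_fraction(assignment.phase, norm.obs["condition"])
    return {
        "label_accuracy": accuracy,
        "sphere_nprog_proportion": float(props.loc["spheres", "NProg-like"]),
        "cycling_fraction_spheres": float(cyc["spheres"]),
        "cycling_fraction_primary": float(cyc["primary"]),
        "n_cells": int(norm.n_obs),
    }


def fidelity_ordering_rate(n_sim: int = 100, n_cells: int = 300, seed: int = 0) -> float:
    """Fraction of simulations with r(primary, TBO) > r(primary, spheres).

    The organoid model shares the primary condition's state proportions;
    the sphere condition is skewed toward the NProg-like state, as in the
    default design. Pseudobulk Pearson correlation over all genes.
    """
    wins = 0
    for i in range(n_sim):
        spec = SyntheticCellSpec(
            n_cells_per_condition=n_cells, seed=derive_seed(seed, "fid", i)
        )
        counts, truth = generate_expression_matrix(spec)
        norm = states.normalize_log(states.matrix_to_anndata(counts, truth["condition"]))
        corr = states.pseudobulk_correlation(states.pseudobulk_profiles(norm))
        wins += corr.loc["primary", "TBO"] > corr.loc["primary", "spheres"]
    return wins / n_sim


def de_recovery(n_cells_per_group: int = 200, n_planted: int = 50, seed: int = 0) -> dict[str, float]:
    """Differential-expression sanity: null specificity and planted recall.

    Two homogeneous conditions built from the simulator: one all in a state
    with an ``n_planted``-gene signature (4-fold up), one undifferentiated.
    The null check splits the undifferentiated condition in half.
    """
    sig = default_signatures(n_per_state=n_planted)
    pure = {"RG-like": 1.0, "NProg-like": 0.0, "Nb-like": 0.0, "undiff": 0.0}
    blank = {"RG-like": 0.0, "NProg-like": 0.0, "Nb-like": 0.0, "undiff": 1.0}
    spec = SyntheticCellSpec(
        n_cells_per_condition=n_cells_per_group,
        conditions=("planted", "reference"),
        state_proportions={"planted": pure, "reference": blank},
        cycling_fraction={"planted": 0.0, "reference": 0.0},
        signature_genes=sig,
        # between-group contrast is fold_change^2 (up in the planted state,
        # repressed in the reference), so 2 yields the 4-fold design
        signature_fold_change=2.0,
        seed=derive_seed(seed, "de"),
    )
    counts, truth = generate_expression_matrix(spec)
    norm = states.normalize_log(states.matrix_to_anndata(counts, truth["condition"]))
    conds = norm.obs["condition"].to_numpy()

    # null: two halves of the same homogeneous condition
    ref_idx = np.flatnonzero(conds == "reference")
    null_table = states.differential_expression(
        norm, np.isin(np.arange(norm.n_obs), ref_idx[::2]),
        np.isin(np.arange(norm.n_obs), ref_idx[1::2]),
    )
    n_null = int((null_table["q"] < 0.05).sum())

    table = states.differential_expression(norm, conds == "planted", conds == "reference")
    planted = set(sig["RG-like"])
    top = set(table.nsmallest(n_planted, "q")["gene"])
    recall = len(top & planted) / n_planted
    return {"null_positives": n_null, "planted_recall": recall}


def wilcoxon_exact_example() -> float:
    """Exact two-sided rank-sum p for the fully separated triples."""
    p, method = screen.test_group_difference([1, 2, 3], [4, 5, 6])
    assert method == "exact"
    return p
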