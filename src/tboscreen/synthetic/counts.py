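"""Synthetic single-cell count matrices with known cell-state structure.

Emulates the transcriptomic comparison of a primary tumor, the organoid
model (TBO) and a tumorsphere culture: each condition is a mixture of four
tumor cell states (RG-like, NProg-like, Nb-like, undifferentiated) in known
proportions, with a known fraction of cycling cells. State identity is
encoded by multiplicative up-regulation of disjoint signature gene sets;
cycling cells additionally up-regulate S-phase or G2M genes. Counts are
negative-binomial with per-gene baselines drawn from a log-normal, and each
cell's expected library size is fixed, so empirical library sizes
concentrate around ``library_size_mean``.

A per-(condition, state) marker knockout option silences chosen genes in a
chosen subpopulation — e.g. removing a neuronal differentiation marker from
tumorsphere Nb-like cells only — so detection-fraction analyses can be
validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STATES = ("RG-like", "NProg-like", "Nb-like", "undiff")


def default_signatures(
    n_per_state: int = 30, n_cycle: int = 20
) -> dict[str, list[str]]:
    """Editable default signature gene sets for the simulator.

    Three state signatures (the undifferentiated state has none, by
    definition) plus S-phase and G2M lists. STMN2, a neuronal
    differentiation marker, is included in the neuroblast-like signature so
    marker-dropout scenarios can target it by name.
    """
    sig = {
        "RG-like": [f"RG{i:03d}" for i in range(1, n_per_state + 1)],
        "NProg-like": [f"NP{i:03d}" for i in range(1, n_per_state + 1)],
        "Nb-like": ["STMN2"] + [f"NB{i:03d}" for i in range(1, n_per_state)],
        "S": [f"S{i:03d}" for i in range(1, n_cycle + 1)],
        "G2M": [f"G2M{i:03d}" for i in range(1, n_cycle + 1)],
    }
    return sig


def _default_proportions() -> dict[str, dict[str, float]]:
    balanced = {"RG-like": 0.25, "NProg-like": 0.25, "Nb-like": 0.25, "undiff": 0.25}
    skewed = {"RG-like": 0.1, "NProg-like": 0.7, "Nb-like": 0.1, "undiff": 0.1}
    return {"primary": dict(balanced), "TBO": dict(balanced), "spheres": skewed}


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Study design of one synthetic scRNA-seq experiment.

    Defaults encode the qualitative structure the analysis is built to
    detect: primary tumor and organoid model share a balanced state mix,
    the tumorsphere condition is skewed toward the NProg-like state
    (70%) and accumulates cycling cells (60% vs 20% elsewhere).
    """

    n_cells_per_condition: int = 1000
    conditions: tuple[str, ...] = ("primary", "TBO", "spheres")
    state_proportions: dict[str, dict[str, float]] = field(
        default_factory=_default_proportions
    )
    cycling_fraction: dict[str, float] = field(
        default_factory=lambda: {"primary": 0.2, "TBO": 0.2, "spheres": 0.6}
    )
    signature_genes: dict[str, list[str]] = field(default_factory=default_signatures)
    signature_fold_change: float = 4.0
    baseline_mean: float = 2.0
    baseline_log_sd: float = 0.6
    #: baseline multiplier for signature/cycle genes: curated marker genes
    #: are chosen for robust detection, so they sit above the typical
    #: background gene's expression even in cells not enriched for them
    marker_baseline_boost: float = 3.0
    dispersion: float = 2.0
    library_size_mean: float = 5000.0
    n_background_genes: int = 2000
    #: {(condition, state): [gene, ...]} — genes silenced in that subpopulation
    knockouts: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for cond in self.conditions:
            props = self.state_proportions[cond]
            if abs(sum(props.values()) - 1.0) > 1e-8:
                raise ValueError(f"state proportions for {cond!r} must sum to 1")
            if set(props) != set(STATES):
                raise ValueError(f"proportions for {cond!r} must cover states {STATES}")
        if self.signature_fold_change < 1.0:
            raise ValueError("signature_fold_change must be >= 1 (1 is the null case)")
        lists = [self.signature_genes[k] for k in sorted(self.signature_genes)]
        flat = [g for gl in lists for g in gl]
        if len(flat) != len(set(flat)):
            raise ValueError("signature gene lists must be pairwise disjoint")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("dispersion and baseline_mean must be positive")


def generate_expression_matrix(
    spec: SyntheticCellSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a gene x cell integer count matrix plus per-cell truth.

    Returns ``(counts, truth)`` where ``counts`` is a genes x cells
    DataFrame and ``truth`` has one row per cell with columns ``condition``,
    ``state``, ``cycling`` and ``phase`` (G1/S/G2M). Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)

    genes = [f"BG{i:04d}" for i in range(1, spec.n_background_genes + 1)]
    sig_names = [k for k in spec.signature_genes if k not in ("S", "G2M")]
    for key in sig_names + ["S", "G2M"]:
        genes.extend(spec.signature_genes[key])
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # per-gene baseline expression, log-normal around baseline_mean
    log_mu = np.log(spec.baseline_mean) - spec.baseline_log_sd**2 / 2
    base = rng.lognormal(mean=log_mu, sigma=spec.baseline_log_sd, size=n_genes)

    sig_idx = {
        key: np.array([gene_index[g] for g in gl])
        for key, gl in spec.signature_genes.items()
    }
    for idx in sig_idx.values():
        base[idx] *= spec.marker_baseline_boost

    cells, rows = [], []
    for cond in spec.conditions:
        props = spec.state_proportions[cond]
        n = spec.n_cells_per_condition
        # deterministic rounded composition, remainder to the largest class
        counts_per_state = {s: int(round(props[s] * n)) for s in STATES}
        drift = n - sum(counts_per_state.values())
        counts_per_state[max(STATES, key=lambda s: props[s])] += drift
        for state in STATES:
            for _ in range(counts_per_state[state]):
                cycling = rng.random() < spec.cycling_fraction[cond]
                phase = rng.choice(["S", "G2M"]) if cycling else "G1"
                rows.append({"condition": cond, "state": state, "cycling": cycling, "phase": phase})

    truth = pd.DataFrame(rows)
    truth.index = [f"cell{i:05d}" for i in range(len(truth))]
    truth.index.name = "cell_id"

    theta = spec.dispersion
    counts = np.empty((n_genes, len(truth)), dtype=np.int64)
    # Signature programs are specific: a cell running a program up-regulates
    # its genes by fold_change, every other cell represses them by the same
    # factor (lineage and cycle genes are largely silent outside their
    # program). At fold_change -> 1 all states collapse to the same profile.
    fc = spec.signature_fold_change
    for j, (cid, cell) in enumerate(truth.iterrows()):
        rate = base.copy()
        for key in sig_names:
            rate[sig_idx[key]] *= fc if cell["state"] == key else 1.0 / fc
        for key in ("S", "G2M"):
            rate[sig_idx[key]] *= fc if cell["phase"] == key else 1.0 / fc
        ko = spec.knockouts.get((cell["condition"], cell["state"]))
        if ko:
            rate[[gene_index[g] for g in ko if g in gene_index]] = 0.0
        mu = rate * (spec.library_size_mean / rate.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            p = theta / (theta + mu)
        draw = np.zeros(n_genes, dtype=np.int64)
        pos = mu > 0
        draw[pos] = rng.negative_binomial(theta, p[pos])
        counts[:, j] = draw

    matrix = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=truth.index)
    return matrix, truth
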