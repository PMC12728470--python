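"""Signature-based tumor cell-state classification and model-fidelity scoring.

Tumor cells are classified into states resembling fetal radial glia
(RG-like), neuronal progenitors (NProg-like) and neuroblasts (Nb-like) by
per-cell *module scores* of user-supplied signature gene sets; cells with no
positive signature enrichment are labelled undifferentiated. The module
score of a gene set is the mean normalized expression of its genes minus
the mean of seeded control genes drawn from expression-matched bins, so a
score near zero means "no enrichment over comparable genes".

On top of the per-cell labels the module computes the fidelity readouts
used to compare a model system against the primary tumor: state proportions
per condition, fraction of cycling cells (S/G2M scoring), pairwise
pseudobulk Pearson correlation between conditions, nonparametric
differential expression, and marker detection fractions per
(state, condition) subset.

Expression is handled as an :class:`anndata.AnnData` (cells x genes) with a
``condition`` column in ``obs``; :func:`matrix_to_anndata` converts a genes
x cells DataFrame (the on-disk orientation) into one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .screen import bh_adjust

UNDIFF = "undiff"
CYCLE_KEYS = ("S", "G2M")


@dataclass
class SignatureSet:
    """Named signature gene lists plus the S-phase and G2M cycle lists."""

    states: dict[str, list[str]]
    s_genes: list[str] = field(default_factory=list)
    g2m_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("at least one state signature required")
        for name, genes in self.states.items():
            if not genes:
                raise ValueError(f"signature {name!r} is empty")
        if len(set(self.states)) != len(self.states):
            raise ValueError("signature names must be unique")

    @classmethod
    def from_dict(cls, sig: dict[str, list[str]]) -> "SignatureSet":
        states = {k: v for k, v in sig.items() if k not in CYCLE_KEYS}
        return cls(states=states, s_genes=sig.get("S", []), g2m_genes=sig.get("G2M", []))

    @property
    def all_genes(self) -> list[str]:
        """Union of every state and cycle gene list (the control exclusion set)."""
        out: list[str] = []
        for genes in self.states.values():
            out.extend(genes)
        out.extend(self.s_genes)
        out.extend(self.g2m_genes)
        return sorted(set(out))


def matrix_to_anndata(
    counts: pd.DataFrame, conditions: pd.Series | None = None
) -> ad.AnnData:
    """Wrap a genes x cells count DataFrame as AnnData (cells x genes)."""
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene names in count matrix")
    adata = ad.AnnData(
        X=counts.to_numpy(dtype=np.float32).T,
        obs=pd.DataFrame(index=counts.columns.astype(str)),
        var=pd.DataFrame(index=counts.index.astype(str)),
    )
    if conditions is not None:
        adata.obs["condition"] = pd.Series(conditions).reindex(adata.obs_names).to_numpy()
    return adata


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def normalize_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Library-size normalization to ``target_sum`` counts per cell + log1p.

    Cells with zero total counts are dropped with a warning. Returns a new
    AnnData with the normalized matrix in ``X`` and raw counts kept in
    ``layers["counts"]``.
    """
    X = _dense(adata.X).astype(np.float64)
    lib = X.sum(axis=1)
    keep = lib > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-count cells", stacklevel=2)
        adata = adata[keep].copy()
        X, lib = X[keep], lib[keep]
    out = adata.copy()
    out.layers["counts"] = X.copy()
    out.X = np.log1p(X * (target_sum / lib[:, None]))
    return out


def score_signature(
    adata: ad.AnnData,
    gene_set: list[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
    exclude: list[str] | None = None,
) -> np.ndarray:
    """Per-cell module score of one gene set on normalized expression.

    Mean expression of the signature genes minus the mean of control genes
    sampled (seeded, without replacement) from expression-matched bins:
    genes are ranked by their mean expression across cells and cut into
    ``n_bins`` equal-size bins; each signature gene contributes up to
    ``n_ctrl`` control genes from its own bin. Deterministic given ``seed``.

    The control pool excludes the signature itself plus any genes in
    ``exclude``. When scoring several signatures side by side, pass the
    union of all of them as ``exclude``: genes of a rival program are
    repressed in the scored cells, and letting them act as controls biases
    every score upward.
    """
    present = [g for g in gene_set if g in adata.var_names]
    missing = [g for g in gene_set if g not in adata.var_names]
    if not present:
        raise ValueError(f"no signature gene present in matrix; missing: {missing}")

    X = _dense(adata.X)
    gene_means = X.mean(axis=0)
    order = pd.Series(gene_means, index=adata.var_names).rank(method="first")
    bins = pd.cut(order, bins=n_bins, labels=False)

    rng = np.random.default_rng(seed)
    sig_set = set(present) | (set(exclude) if exclude else set())
    ctrl: set[str] = set()
    for g in present:
        pool = bins.index[(bins == bins[g]) & ~bins.index.isin(sig_set)]
        if len(pool) == 0:
            continue
        take = min(n_ctrl, len(pool))
        ctrl.update(rng.choice(pool.to_numpy(), size=take, replace=False))
    if not ctrl:
        raise ValueError("no control genes available outside the signature")

    var_idx = {g: i for i, g in enumerate(adata.var_names)}
    sig_mean = X[:, [var_idx[g] for g in present]].mean(axis=1)
    ctrl_mean = X[:, [var_idx[g] for g in sorted(ctrl)]].mean(axis=1)
    return sig_mean - ctrl_mean


def score_all_signatures(
    adata: ad.AnnData,
    signatures: SignatureSet,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Module scores for every state signature; one column per state.

    Controls are drawn outside the union of all signature and cycle lists.
    """
    exclude = signatures.all_genes
    scores = {
        name: score_signature(adata, genes, n_bins=n_bins, n_ctrl=n_ctrl,
                              seed=seed + i, exclude=exclude)
        for i, (name, genes) in enumerate(signatures.states.items())
    }
    return pd.DataFrame(scores, index=adata.obs_names)


def assign_states(scores: pd.DataFrame, threshold: float = 0.0) -> pd.Series:
    """Label each cell by its top-scoring signature, or undifferentiated.

    The label is the argmax signature when the maximum score exceeds
    ``threshold`` (default 0: any positive enrichment wins), otherwise
    ``undiff``. Ties are broken by the fixed column order of ``scores``.
    """
    best = scores.to_numpy().argmax(axis=1)  # first occurrence wins ties
    maxval = scores.to_numpy().max(axis=1)
    labels = np.where(maxval > threshold, scores.columns.to_numpy()[best], UNDIFF)
    return pd.Series(labels, index=scores.index, name="state")


@dataclass
class CellStateAssignment:
    """Per-cell scores, state label, cycle phase and cycling flag."""

    scores: pd.DataFrame
    labels: pd.Series
    phase: pd.Series
    threshold: float

    @property
    def cycling(self) -> pd.Series:
        return (self.phase != "G1").rename("cycling")

    def frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        out["state"] = self.labels
        out["phase"] = self.phase
        out["cycling"] = self.cycling
        return out


def cycle_phase(
    adata: ad.AnnData,
    s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
    exclude: list[str] | None = None,
) -> pd.Series:
    """Cell-cycle phase per cell: S or G2M when that score is positive
    (argmax of the two), else G1. Cells with no expressed cycle genes are G1.

    ``exclude`` extends the control exclusion set; the two cycle lists
    always exclude each other.
    """
    excl = sorted(set(s_genes) | set(g2m_genes) | (set(exclude) if exclude else set()))
    try:
        s = score_signature(adata, s_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed, exclude=excl)
    except ValueError:
        s = np.full(adata.n_obs, -np.inf)
    try:
        g2m = score_signature(adata, g2m_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + 1, exclude=excl)
    except ValueError:
        g2m = np.full(adata.n_obs, -np.inf)
    both = np.column_stack([s, g2m])
    phase = np.where(both.max(axis=1) > 0, np.array(["S", "G2M"])[both.argmax(axis=1)], "G1")
    return pd.Series(phase, index=adata.obs_names, name="phase")


def classify(
    adata: ad.AnnData,
    signatures: SignatureSet,
    threshold: float = 0.0,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> CellStateAssignment:
    """Full per-cell assignment: state scores + label + cycle phase."""
    scores = score_all_signatures(adata, signatures, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    labels = assign_states(scores, threshold=threshold)
    if signatures.s_genes and signatures.g2m_genes:
        phase = cycle_phase(
            adata, signatures.s_genes, signatures.g2m_genes,
            n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + 1000,
            exclude=signatures.all_genes,
        )
    else:
        phase = pd.Series("G1", index=adata.obs_names, name="phase")
    return CellStateAssignment(scores=scores, labels=labels, phase=phase, threshold=threshold)


def state_proportions(
    labels: pd.Series, conditions: pd.Series, states: list[str] | None = None
) -> pd.DataFrame:
    """Per-condition fraction of cells in each state (rows sum to 1).

    Conditions with no cells are excluded with a warning.
    """
    df = pd.DataFrame({"state": labels, "condition": conditions}).dropna()
    if isinstance(conditions.dtype, pd.CategoricalDtype):
        declared = set(conditions.cat.categories)
    else:
        declared = set(pd.unique(conditions.dropna()))
    empty = declared - set(df["condition"])
    if empty:
        warnings.warn(f"conditions with no cells excluded: {sorted(empty)}", stacklevel=2)
    table = pd.crosstab(df["condition"], df["state"], normalize="index")
    if states is not None:
        table = table.reindex(columns=states, fill_value=0.0)
    return table


def cycling_fraction(phase: pd.Series, conditions: pd.Series) -> pd.Series:
    """Fraction of cycling (non-G1) cells per condition."""
    df = pd.DataFrame({"cycling": phase != "G1", "condition": conditions}).dropna()
    return df.groupby("condition", observed=True)["cycling"].mean()


def pseudobulk_profiles(adata: ad.AnnData, condition_key: str = "condition") -> pd.DataFrame:
    """Per-condition pseudobulk: mean normalized expression across cells.

    Returns genes x conditions.
    """
    X = _dense(adata.X)
    conds = adata.obs[condition_key]
    out = {}
    for cond in pd.unique(conds.dropna()):
        out[cond] = X[(conds == cond).to_numpy()].mean(axis=0)
    return pd.DataFrame(out, index=adata.var_names)


def pseudobulk_correlation(
    profiles: pd.DataFrame, genes: list[str] | None = None, top_k: int | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix between pseudobulk profiles.

    Optionally restricted to a gene list or to the ``top_k`` most variable
    genes across conditions (default: all shared genes). Zero-variance
    profiles are an error (correlation undefined).
    """
    prof = profiles.loc[genes] if genes is not None else profiles
    if len(prof) < 2:
        raise ValueError("need at least two shared genes")
    if top_k is not None:
        var = prof.var(axis=1)
        prof = prof.loc[var.nlargest(top_k).index]
    sds = prof.std(axis=0)
    flat = sds[sds == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance pseudobulk profile(s): {flat}")
    return prof.corr(method="pearson")


def differential_expression(
    adata: ad.AnnData,
    group_a: np.ndarray | pd.Series,
    group_b: np.ndarray | pd.Series,
    pseudocount: float = 1.0,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between two cell groups.

    ``group_a``/``group_b`` are boolean masks (or cell-name lists) over
    ``adata.obs_names``. Per gene: two-sided rank-sum test on normalized
    expression (normal approximation with tie correction — counts data are
    tie-heavy), log2 fold change of group means with a pseudocount, and BH
    adjustment across tested genes. Genes that are all-zero in both groups
    are excluded and counted in ``attrs["n_excluded"]``.
    """
    def to_mask(sel) -> np.ndarray:
        arr = np.asarray(sel)
        if arr.dtype == bool:
            return arr
        return adata.obs_names.isin(arr)

    ma, mb = to_mask(group_a), to_mask(group_b)
    if ma.sum() < min_cells or mb.sum() < min_cells:
        raise ValueError(f"both groups need >= {min_cells} cells")
    if (ma & mb).any():
        raise ValueError("groups overlap")

    X = _dense(adata.X)
    A, B = X[ma], X[mb]
    expressed = (A.sum(axis=0) + B.sum(axis=0)) > 0
    n_excluded = int((~expressed).sum())
    A, B = A[:, expressed], B[:, expressed]

    res = stats.mannwhitneyu(A, B, alternative="two-sided", method="asymptotic", axis=0)
    log2fc = np.log2((A.mean(axis=0) + pseudocount) / (B.mean(axis=0) + pseudocount))
    table = pd.DataFrame(
        {
            "gene": np.asarray(adata.var_names)[expressed],
            "log2_fold_change": log2fc,
            "p": res.pvalue,
            "q": bh_adjust(res.pvalue),
            "mean_a": A.mean(axis=0),
            "mean_b": B.mean(axis=0),
        }
    ).sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)
    table.attrs["n_excluded"] = n_excluded
    return table


def marker_presence(
    adata: ad.AnnData,
    labels: pd.Series,
    gene: str,
    condition_key: str = "condition",
) -> pd.DataFrame:
    """Detection fraction of ``gene`` per (condition, state) cell subset.

    The fraction of cells with expression > 0; empty subsets are reported
    as NaN (missing) rather than 0.
    """
    if gene not in adata.var_names:
        raise ValueError(f"gene {gene!r} not present in matrix")
    expr = _dense(adata[:, [gene]].X).ravel()
    df = pd.DataFrame(
        {
            "condition": adata.obs[condition_key].to_numpy(),
            "state": labels.reindex(adata.obs_names).to_numpy(),
            "detected": expr > 0,
        }
    )
    table = df.pivot_table(
        index="condition", columns="state", values="detected", aggfunc="mean", dropna=False
    )
    return table
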