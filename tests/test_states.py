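"""Cell-state scoring, assignment and fidelity readouts."""

from dataclasses import replace

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from tboscreen import states
from tboscreen.synthetic import SyntheticCellSpec, generate_expression_matrix


@pytest.fixture(scope="module")
def small_dataset():
    """One simulated experiment shared by the classification tests."""
    spec = SyntheticCellSpec(n_cells_per_condition=200, seed=9)
    counts, truth = generate_expression_matrix(spec)
    adata = states.matrix_to_anndata(counts, truth["condition"])
    norm = states.normalize_log(adata)
    sigs = states.SignatureSet.from_dict(spec.signature_genes)
    return spec, norm, truth, sigs


# ------------------------------------------------------------ normalization

def test_normalize_matches_naive_oracle():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.poisson(3, size=(20, 8)),
        index=[f"g{i}" for i in range(20)],
        columns=[f"c{i}" for i in range(8)],
    )
    counts.iloc[:, 0] += 1  # guard against an all-zero first cell
    adata = states.matrix_to_anndata(counts)
    norm = states.normalize_log(adata)
    for j, cell in enumerate(norm.obs_names):
        raw = counts[cell].to_numpy(dtype=float)
        expected = np.log1p(raw / raw.sum() * 1e4)
        np.testing.assert_allclose(norm.X[j], expected, rtol=1e-12)


def test_proportional_cells_normalize_identically():
    counts = pd.DataFrame(
        {"a": [1, 2, 3, 0], "b": [3, 6, 9, 0]}, index=["g1", "g2", "g3", "g4"]
    )
    norm = states.normalize_log(states.matrix_to_anndata(counts))
    np.testing.assert_allclose(norm.X[0], norm.X[1], rtol=1e-12)
    assert norm.X[0][3] == 0.0  # zero count stays zero


def test_zero_count_cells_dropped_with_warning():
    counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]}, index=["g1", "g2"])
    with pytest.warns(UserWarning, match="zero-count"):
        norm = states.normalize_log(states.matrix_to_anndata(counts))
    assert list(norm.obs_names) == ["a"]


# ------------------------------------------------------------------ scoring

def test_missing_signature_genes_error(small_dataset):
    _, norm, _, _ = small_dataset
    with pytest.raises(ValueError, match="ABSENT1"):
        states.score_signature(norm, ["ABSENT1", "ABSENT2"])


def test_scores_deterministic_given_seed(small_dataset):
    spec, norm, _, sigs = small_dataset
    s1 = states.score_signature(norm, sigs.states["RG-like"], seed=3)
    s2 = states.score_signature(norm, sigs.states["RG-like"], seed=3)
    np.testing.assert_array_equal(s1, s2)
    s3 = states.score_signature(norm, sigs.states["RG-like"], seed=4)
    assert not np.array_equal(s1, s3)


def test_null_data_scores_center_at_zero():
    # true null: no state structure and signature genes drawn from the same
    # baseline distribution as the control pool
    spec = SyntheticCellSpec(
        n_cells_per_condition=150, signature_fold_change=1.0,
        marker_baseline_boost=1.0, seed=2,
    )
    counts, truth = generate_expression_matrix(spec)
    norm = states.normalize_log(states.matrix_to_anndata(counts, truth["condition"]))
    sigs = states.SignatureSet.from_dict(spec.signature_genes)
    scores = states.score_all_signatures(norm, sigs, seed=0)
    assert np.abs(scores.mean(axis=0)).max() < 0.1


def test_own_signature_scores_dominate(small_dataset):
    spec, norm, truth, sigs = small_dataset
    scores = states.score_all_signatures(norm, sigs, seed=1)
    for state in sigs.states:
        own = scores.loc[(truth["state"] == state).to_numpy(), state]
        other_cells = (truth["state"] != state).to_numpy()
        other = scores.loc[other_cells, state]
        # AUC of own-state vs other cells on this state's score
        auc = (own.to_numpy()[:, None] > other.to_numpy()[None, :]).mean()
        assert auc >= 0.95


def test_score_invariant_to_cell_order(small_dataset):
    _, norm, _, sigs = small_dataset
    perm = np.random.default_rng(0).permutation(norm.n_obs)
    shuffled = norm[perm].copy()
    s_orig = states.score_signature(norm, sigs.states["Nb-like"], seed=5)
    s_shuf = states.score_signature(shuffled, sigs.states["Nb-like"], seed=5)
    np.testing.assert_allclose(s_shuf, s_orig[perm], rtol=1e-12)


def test_scores_track_scanpy_reference(small_dataset):
    """Independent cross-check: scanpy's module scorer ranks cells the same."""
    sc = pytest.importorskip("scanpy")
    _, norm, _, sigs = small_dataset
    ours = states.score_signature(norm, sigs.states["RG-like"], seed=0)
    ref = norm.copy()
    sc.tl.score_genes(ref, sigs.states["RG-like"], score_name="ref", random_state=0)
    r = np.corrcoef(ours, ref.obs["ref"])[0, 1]
    assert r > 0.98


# --------------------------------------------------------------- assignment

def test_all_nonpositive_scores_give_undiff():
    scores = pd.DataFrame({"A": [-1.0, -0.2], "B": [0.0, -0.5]})
    labels = states.assign_states(scores)
    assert (labels == states.UNDIFF).all()


def test_infinite_threshold_gives_all_undiff(small_dataset):
    spec, norm, _, sigs = small_dataset
    scores = states.score_all_signatures(norm, sigs, seed=0)
    labels = states.assign_states(scores, threshold=np.inf)
    assert (labels == states.UNDIFF).all()


def test_ties_broken_by_signature_order():
    scores = pd.DataFrame({"B": [0.7], "A": [0.7]})
    assert states.assign_states(scores).iloc[0] == "B"


def test_assignment_recovers_true_states(small_dataset):
    spec, norm, truth, sigs = small_dataset
    assignment = states.classify(norm, sigs, seed=0)
    accuracy = (assignment.labels.to_numpy() == truth["state"].to_numpy()).mean()
    assert accuracy >= 0.9


# ------------------------------------------------------------------ cycling

def test_no_cycle_genes_expressed_gives_all_g1():
    counts = pd.DataFrame(
        {"c1": [5, 3, 0, 0], "c2": [2, 4, 0, 0]},
        index=["g1", "g2", "S1", "G2M1"],
    )
    norm = states.normalize_log(states.matrix_to_anndata(counts))
    phase = states.cycle_phase(norm, ["S1"], ["G2M1"])
    assert (phase == "G1").all()


def test_cycling_fraction_recovery(small_dataset):
    spec, norm, truth, sigs = small_dataset
    assignment = states.classify(norm, sigs, seed=0)
    rec = states.cycling_fraction(assignment.phase, truth["condition"])
    true = truth.groupby("condition")["cycling"].mean()
    for cond in spec.conditions:
        assert rec[cond] == pytest.approx(true[cond], abs=0.06)


# -------------------------------------------------------------- proportions

def test_single_state_condition():
    labels = pd.Series(["RG-like"] * 5, index=[f"c{i}" for i in range(5)])
    conds = pd.Series(["primary"] * 5, index=labels.index)
    props = states.state_proportions(labels, conds)
    assert props.loc["primary", "RG-like"] == 1.0


def test_proportions_sum_to_one(small_dataset):
    spec, norm, truth, sigs = small_dataset
    assignment = states.classify(norm, sigs, seed=0)
    props = states.state_proportions(assignment.labels, truth["condition"])
    np.testing.assert_allclose(props.sum(axis=1), 1.0, rtol=1e-12)


def test_empty_condition_excluded_with_warning():
    labels = pd.Series(["RG-like", "Nb-like"], index=["c1", "c2"])
    conds = pd.Series(["primary", "primary"], index=labels.index).astype(
        pd.CategoricalDtype(["primary", "ghost"])
    )
    with pytest.warns(UserWarning, match="ghost"):
        props = states.state_proportions(labels, conds)
    assert list(props.index) == ["primary"]


# --------------------------------------------------------------- pseudobulk

def test_pseudobulk_self_correlation_is_one(small_dataset):
    _, norm, _, _ = small_dataset
    prof = states.pseudobulk_profiles(norm)
    corr = states.pseudobulk_correlation(prof)
    np.testing.assert_allclose(np.diag(corr), 1.0, rtol=1e-12)
    assert corr.to_numpy().min() >= -1 and corr.to_numpy().max() <= 1 + 1e-12


def test_independent_profiles_correlate_near_zero():
    rng = np.random.default_rng(1)
    prof = pd.DataFrame(rng.normal(size=(4000, 2)), columns=["a", "b"])
    r = states.pseudobulk_correlation(prof).loc["a", "b"]
    assert abs(r) < 0.05


def test_zero_variance_profile_rejected():
    prof = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="zero-variance"):
        states.pseudobulk_correlation(prof)


def test_fidelity_ordering_on_default_design(small_dataset):
    """The organoid model shares the primary state mix, spheres are skewed:
    primary-vs-model correlation must exceed primary-vs-spheres."""
    _, norm, _, _ = small_dataset
    corr = states.pseudobulk_correlation(states.pseudobulk_profiles(norm))
    assert corr.loc["primary", "TBO"] > corr.loc["primary", "spheres"]


# ----------------------------------------------------- differential expression

def test_de_antisymmetry_and_null(small_dataset):
    _, norm, truth, _ = small_dataset
    primary = (truth["condition"] == "primary").to_numpy()
    half1 = primary & (np.arange(len(primary)) % 2 == 0)
    half2 = primary & (np.arange(len(primary)) % 2 == 1)
    ab = states.differential_expression(norm, half1, half2)
    ba = states.differential_expression(norm, half2, half1)
    merged = ab.merge(ba, on="gene", suffixes=("_ab", "_ba"))
    np.testing.assert_allclose(
        merged["log2_fold_change_ab"], -merged["log2_fold_change_ba"], atol=1e-12
    )
    assert (ab["q"] < 0.05).sum() == 0  # same population split in half


def test_de_finds_planted_signature_genes(small_dataset):
    spec, norm, truth, sigs = small_dataset
    rg = (truth["state"] == "RG-like").to_numpy()
    undiff = (truth["state"] == "undiff").to_numpy()
    table = states.differential_expression(norm, rg, undiff)
    top = set(table.nsmallest(30, "q")["gene"])
    assert len(top & set(sigs.states["RG-like"])) >= 27
    sig_rows = table[table["gene"].isin(sigs.states["RG-like"])]
    assert (sig_rows["log2_fold_change"] > 0).all()


def test_de_rejects_overlapping_or_tiny_groups(small_dataset):
    _, norm, _, _ = small_dataset
    mask = np.zeros(norm.n_obs, dtype=bool)
    mask[:10] = True
    with pytest.raises(ValueError, match="overlap"):
        states.differential_expression(norm, mask, mask)
    with pytest.raises(ValueError, match=">= 3"):
        states.differential_expression(norm, mask, np.zeros(norm.n_obs, dtype=bool))


# ------------------------------------------------------------------ markers

def test_marker_absent_everywhere_gives_zero(small_dataset):
    _, norm, truth, sigs = small_dataset
    zero = norm.copy()
    idx = list(zero.var_names).index("STMN2")
    zero.X[:, idx] = 0.0
    labels = pd.Series("Nb-like", index=zero.obs_names)
    table = states.marker_presence(zero, labels, "STMN2")
    assert (table.fillna(0) == 0).all().all()


def test_marker_knockout_detected_per_condition():
    spec = SyntheticCellSpec(
        n_cells_per_condition=150,
        knockouts={("spheres", "Nb-like"): ["STMN2"]},
        seed=4,
    )
    counts, truth = generate_expression_matrix(spec)
    norm = states.normalize_log(states.matrix_to_anndata(counts, truth["condition"]))
    table = states.marker_presence(
        norm, truth["state"].reindex(norm.obs_names), "STMN2"
    )
    assert table.loc["spheres", "Nb-like"] < 0.05
    assert table.loc["TBO", "Nb-like"] > 0.5
    valid = table.to_numpy()[~np.isnan(table.to_numpy())]
    assert ((valid >= 0) & (valid <= 1)).all()


def test_unknown_marker_rejected(small_dataset):
    _, norm, truth, _ = small_dataset
    with pytest.raises(ValueError, match="NOPE"):
        states.marker_presence(norm, truth["state"], "NOPE")
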