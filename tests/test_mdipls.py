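"""The MdiPLS predictor: weight extraction, MIL loop, deflation, scoring."""

import numpy as np
import pytest

from isofrog.data_model import GeneIsoformMap, PredictionTask
from isofrog.mdipls import (
    FitError,
    MdiplsConfig,
    fit,
    fit_weight_vector,
    load_model,
    mil_update,
    predict,
    save_model,
    scores_to_probabilities,
)
from .conftest import make_planted_task, make_sig_task, nipals_pls1


class TestWeightVector:
    def test_lambda_zero_is_pls1_weight(self, rng):
        task = make_sig_task(rng, n_g=30, n_f=8)
        w = fit_weight_vector(task.Xg, task.yg, task.Xiso, 0.0)
        ref = task.Xg.T @ task.yg
        cos = w @ ref / np.linalg.norm(ref)
        assert cos > 1 - 1e-8

    def test_identical_domains_reduce_to_pls1(self, rng):
        task = make_sig_task(rng, n_g=30, n_f=8)
        w0 = fit_weight_vector(task.Xg, task.yg, task.Xg, 0.0)
        w = fit_weight_vector(task.Xg, task.yg, task.Xg, 100.0)
        assert np.max(np.abs(w - w0)) < 1e-6

    def test_regularizer_shrinks_variance_gap_under_domain_shift(self, rng):
        task = make_sig_task(rng, n_g=40, n_f=10)
        X_target = task.Xiso * 3.0  # planted variance shift

        def gap(lam):
            w = fit_weight_vector(task.Xg, task.yg, X_target, lam)
            return abs(np.var(task.Xg @ w, ddof=1) - np.var(X_target @ w, ddof=1))

        assert gap(100.0) < gap(0.0)

    def test_degenerate_inputs_rejected(self, rng):
        task = make_sig_task(rng, n_g=10, n_f=4)
        with pytest.raises(FitError):
            fit_weight_vector(np.zeros((10, 4)), task.yg[:10], task.Xiso, 1.0)
        with pytest.raises(FitError):
            fit_weight_vector(task.Xg, task.yg, task.Xiso, -1.0)

    def test_unit_norm(self, rng):
        task = make_sig_task(rng, n_g=30, n_f=8)
        for lam in (0.0, 1.0, 50.0):
            w = fit_weight_vector(task.Xg, task.yg, task.Xiso, lam)
            assert abs(np.linalg.norm(w) - 1) < 1e-12


def _mil_fixture(seed=0, n_pos_mig=8, n_f=12):
    """Positive MIGs whose responsible isoform copies a positive-SIG profile
    exactly; decoy isoforms are independent noise."""
    rng = np.random.default_rng(seed)
    n_sig = 30
    sig_genes = [f"s{i}" for i in range(n_sig)]
    y_sig = np.r_[np.ones(10), np.zeros(20)]
    X_sig = rng.normal(size=(n_sig, n_f))
    X_sig[y_sig == 1] += 2.0  # positive SIG signature

    genes, isos, pairs, rows, truth = list(sig_genes), [], [], [], {}
    for g, x in zip(sig_genes, X_sig):
        iso = f"{g}.1"
        isos.append(iso)
        pairs.append((g, iso))
        rows.append(x)
    y = list(y_sig)
    for i in range(n_pos_mig):
        g = f"m{i}"
        genes.append(g)
        y.append(1.0)
        donor = X_sig[rng.integers(0, 10)]
        resp = f"{g}.1"
        truth[g] = resp
        for j, profile in enumerate([donor, rng.normal(size=n_f), rng.normal(size=n_f)]):
            iso = f"{g}.{j + 1}"
            isos.append(iso)
            pairs.append((g, iso))
            rows.append(profile)
    # a few negative MIGs so the initial stack has MIG rows too
    for i in range(4):
        g = f"n{i}"
        genes.append(g)
        y.append(0.0)
        for j in range(2):
            iso = f"{g}.{j + 1}"
            isos.append(iso)
            pairs.append((g, iso))
            rows.append(rng.normal(size=n_f))

    Xiso = np.array(rows)
    Xg = np.vstack([X_sig, rng.normal(size=(n_pos_mig + 4, n_f)) + 0.0])
    # gene rows of MIGs: sum of their isoforms
    mapping = GeneIsoformMap.from_pairs(pairs)
    iso_row = {t: k for k, t in enumerate(isos)}
    for gi, g in enumerate(genes):
        if g.startswith(("m", "n")):
            Xg[gi] = Xiso[[iso_row[t] for t in mapping.isoforms_of[g]]].sum(axis=0)
    return PredictionTask(
        term_id="GO:MIL",
        gene_ids=genes,
        iso_ids=isos,
        col_ids=[f"e{j}" for j in range(n_f)],
        Xg=Xg - Xg.mean(axis=0),
        Xiso=Xiso - Xiso.mean(axis=0),
        yg=np.asarray(y),
        mapping=mapping,
        gene_col_means=Xg.mean(axis=0),
        iso_col_means=Xiso.mean(axis=0),
    ), truth


class TestMilUpdate:
    def test_copied_positive_profiles_are_selected_quickly(self):
        task, truth = _mil_fixture(seed=3)
        state = mil_update(task, MdiplsConfig())
        assert state.converged and state.n_iterations <= 3
        hits = sum(state.selected[g] == iso for g, iso in truth.items())
        assert hits == len(truth)

    def test_no_positive_migs_degenerates_to_initial_stack(self):
        task, _ = make_planted_task(seed=5, n_mig=10, positive_fraction=0.2)
        # relabel all MIGs negative by rebuilding yg
        yg = task.yg.copy()
        for g in task.mapping.migs:
            yg[task.gene_index[g]] = 0.0
        task = PredictionTask(
            term_id=task.term_id, gene_ids=task.gene_ids, iso_ids=task.iso_ids,
            col_ids=task.col_ids, Xg=task.Xg, Xiso=task.Xiso, yg=yg,
            mapping=task.mapping, gene_col_means=task.gene_col_means,
            iso_col_means=task.iso_col_means,
        )
        state = mil_update(task, MdiplsConfig())
        assert state.selected == {} and state.n_iterations == 1
        expected = len(task.mapping.sigs) + sum(
            len(task.mapping.isoforms_of[g]) for g in task.mapping.migs
        )
        assert state.X_ts.shape[0] == expected
        # SIG isoform labels equal their gene labels
        for iso, label in zip(state.iso_ids, state.y_ts):
            gene = task.mapping.gene_of[iso]
            if gene in task.mapping.sigs:
                assert label == task.label_of_gene(gene)

    def test_iteration_cap_halts_with_warning(self):
        task, _ = _mil_fixture(seed=1)
        cfg = MdiplsConfig(max_mil_iterations=1)
        with pytest.warns(UserWarning, match="did not converge"):
            state = mil_update(task, cfg)
        assert state.n_iterations == 1 and not state.converged

    def test_no_positive_sigs_falls_back_to_gene_rows(self):
        task, truth = _mil_fixture(seed=2)
        yg = task.yg.copy()
        for g in task.mapping.sigs:  # demote every positive SIG
            yg[task.gene_index[g]] = 0.0
        task = PredictionTask(
            term_id=task.term_id, gene_ids=task.gene_ids, iso_ids=task.iso_ids,
            col_ids=task.col_ids, Xg=task.Xg, Xiso=task.Xiso, yg=yg,
            mapping=task.mapping, gene_col_means=task.gene_col_means,
            iso_col_means=task.iso_col_means,
        )
        with pytest.warns(UserWarning, match="no positive SIGs"):
            state = mil_update(task, MdiplsConfig())
        assert set(state.selected) == set(truth)


class TestFit:
    def test_full_rank_lambda0_equals_ols(self, rng):
        task = make_sig_task(rng, n_g=50, n_f=10)
        cfg = MdiplsConfig(n_components=10, lambda_reg=0.0, mil_enabled=False)
        model = fit(task, cfg)
        fitted = task.Xg @ model.b
        ols = task.Xg @ np.linalg.lstsq(task.Xg, task.yg, rcond=None)[0]
        assert np.max(np.abs(fitted - ols)) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nipals_pls1_oracle(self, seed):
        rng = np.random.default_rng(seed)
        task = make_sig_task(rng, n_g=50, n_f=10)
        cfg = MdiplsConfig(n_components=4, lambda_reg=0.0, mil_enabled=False)
        model = fit(task, cfg)
        b_ref = nipals_pls1(task.Xg, task.yg, 4)
        scores = predict(model, task.Xiso + task.iso_col_means)
        ref = task.Xiso @ b_ref
        assert np.max(np.abs(scores - ref)) < 1e-8

    @pytest.mark.parametrize("mil,lam", [(False, 0.0), (False, 2.0), (True, 1.0)])
    def test_b_consistent_with_componentwise_accumulation(self, mil, lam):
        task, _ = make_planted_task(seed=11)
        cfg = MdiplsConfig(n_components=5, lambda_reg=lam, mil_enabled=mil)
        model = fit(task, cfg)
        b_pred = model.train_X @ model.b
        assert np.max(np.abs(b_pred - model.train_response_pred)) < 1e-8

    def test_too_many_components_rejected(self, rng):
        task = make_sig_task(rng, n_g=20, n_f=5)
        with pytest.raises(FitError, match="n_components"):
            fit(task, MdiplsConfig(n_components=6, mil_enabled=False))

    def test_prediction_invariant_to_isoform_row_order(self):
        task, _ = make_planted_task(seed=13)
        perm = np.random.default_rng(0).permutation(len(task.iso_ids))
        permuted = PredictionTask(
            term_id=task.term_id, gene_ids=task.gene_ids,
            iso_ids=[task.iso_ids[i] for i in perm],
            col_ids=task.col_ids, Xg=task.Xg, Xiso=task.Xiso[perm],
            yg=task.yg, mapping=task.mapping,
            gene_col_means=task.gene_col_means,
            iso_col_means=task.iso_col_means,
        )
        cfg = MdiplsConfig()
        s1 = predict(fit(task, cfg), task.Xiso + task.iso_col_means)
        s2 = predict(fit(permuted, cfg), permuted.Xiso + task.iso_col_means)
        assert np.allclose(s1[perm], s2, atol=1e-9)


class TestPredict:
    def test_zero_b_gives_zero_scores(self):
        task, _ = make_planted_task(seed=1)
        model = fit(task, MdiplsConfig(mil_enabled=False))
        model.b = np.zeros_like(model.b)
        assert np.all(predict(model, task.Xiso + task.iso_col_means) == 0)

    def test_hand_computed_dot_product(self):
        task, _ = make_planted_task(seed=1, n_features=2, n_informative=1)
        model = fit(task, MdiplsConfig(n_components=2, mil_enabled=False))
        model.b = np.array([0.5, 0.25])
        model.column_means = np.zeros(2)
        assert predict(model, np.array([[1.0, -1.0]]))[0] == pytest.approx(0.25)

    def test_duplicated_rows_identical_scores_and_shape_check(self):
        task, _ = make_planted_task(seed=1)
        model = fit(task, MdiplsConfig(mil_enabled=False))
        row = task.Xiso[0] + task.iso_col_means
        s = predict(model, np.vstack([row, row]))
        assert s[0] == s[1]
        with pytest.raises(FitError, match="feature columns"):
            predict(model, np.zeros((2, task.n_features + 1)))


class TestProbabilities:
    def test_symmetry_monotonicity_threshold(self):
        s = np.array([-5.0, -0.1, 0.0, 0.1, 5.0])
        p = scores_to_probabilities(s)
        assert p[2] == 0.5
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0.5) == (s > 0))
        assert scores_to_probabilities(np.array([50.0]))[0] > 1 - 1e-10

    def test_standardization_centers_the_decision(self):
        s = np.array([10.0, 11.0, 12.0])
        p = scores_to_probabilities(s, standardize=True)
        assert p[0] < 0.5 < p[2]


def test_model_serialization_round_trip(tmp_path):
    task, _ = make_planted_task(seed=4)
    model = fit(task, MdiplsConfig())
    path = tmp_path / "model.json"
    save_model(model, path)
    back = load_model(path)
    assert np.allclose(back.b, model.b)
    assert np.allclose(back.W, model.W)
    assert back.col_ids == model.col_ids
    assert back.selected_positive_isoforms == model.selected_positive_isoforms
    s1 = predict(model, task.Xiso + task.iso_col_means)
    s2 = predict(back, task.Xiso + task.iso_col_means)
    assert np.allclose(s1, s2)
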