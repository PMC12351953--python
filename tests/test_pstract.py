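import numpy as np
import pandas as pd
import pytest

from scanact.core_io import ExpressionPanel
from scanact.pstract import (
    RESIDUES,
    ResidueSubstitutionModel,
    build_ligandome_index,
    cr_profile,
    residue_entropy,
    s_cr,
    s_cr_diff,
    s_sim,
)
from scanact.synthfix import synthetic_substitution_model


def lig_rows(rows):
    return pd.DataFrame(
        rows,
        columns=["peptide", "allele", "parent", "presentation_score", "affinity_percentile"],
    )


class TestLigandomeIndex:
    def test_observed_overrides_presentation_floor(self):
        obs = lig_rows([("AAAAAAAAA", "A*01:01", "P1", 0.1, 0.5)])
        pred = lig_rows([("AAAAAAAAA", "A*01:01", "P1", 0.1, 0.5)])
        idx = build_ligandome_index(obs, pred)
        assert len(idx.records) == 1
        assert idx.records.iloc[0]["source"] == "observed"

    def test_predicted_only_at_boundary_removed(self):
        pred = lig_rows([("CCCCCCCCC", "A*01:01", "P1", 0.5, 0.5)])
        idx = build_ligandome_index(lig_rows([]), pred)
        assert idx.records.empty

    def test_duplicates_collapse(self):
        obs = lig_rows(
            [
                ("AAAAAAAAA", "A*01:01", "P1", 0.9, 0.5),
                ("AAAAAAAAA", "A*01:01", "P1", 0.9, 0.5),
            ]
        )
        idx = build_ligandome_index(obs, lig_rows([]))
        assert len(idx.records) == 1

    def test_bad_allele_names_dropped_with_warning(self):
        obs = lig_rows([("AAAAAAAAA", "A*01", "P1", 0.9, 0.5)])
        with pytest.warns(UserWarning, match="4-digit"):
            idx = build_ligandome_index(obs, lig_rows([]))
        assert idx.records.empty

    def test_affinity_percentile_filter_on_predictions(self):
        pred = lig_rows([("CCCCCCCCC", "A*01:01", "P1", 0.9, 2.5)])
        idx = build_ligandome_index(lig_rows([]), pred)
        assert idx.records.empty


class TestEntropy:
    def test_constant_column_zero(self):
        assert residue_entropy(["AAAAAAAAA"] * 5, 9)[0] == 0.0

    def test_uniform_over_twenty_is_one(self):
        peps = [r * 9 for r in RESIDUES]
        h = residue_entropy(peps, 9)
        assert np.allclose(h, 1.0)

    def test_fifty_fifty_closed_form(self):
        h = residue_entropy(["AAAAAAAAA", "CAAAAAAAA"], 9)
        assert h[0] == pytest.approx(np.log(2) / np.log(20))
        assert np.allclose(h[1:], 0.0)

    def test_single_peptide_warns_zero_vector(self):
        with pytest.warns(UserWarning):
            h = residue_entropy(["AAAAAAAAA"], 9)
        assert np.allclose(h, 0.0)


def toy_model():
    """2-letter-relevant toy model embedded in the full 20x20 frame."""
    pm = pd.DataFrame(np.eye(20) * 2.0, index=RESIDUES, columns=RESIDUES)
    pm.loc["A", "C"] = pm.loc["C", "A"] = 1.5
    emb = pd.DataFrame(np.zeros((20, 9)), index=RESIDUES)
    emb.loc["C", 0] = 1.0
    emb.loc["D", 0] = 5.0
    return ResidueSubstitutionModel(pmbec=pm, embedding=emb)


def oracle_s_sim(tumoral, normals, model, entropy):
    """From-scratch recomputation of both similarity components."""

    def comp(dist):
        out = []
        for pn in normals:
            vals = [
                (1.0 / (1.0 + dist(a, b))) * (1.0 + h)
                for a, b, h in zip(tumoral, pn, entropy)
            ]
            out.append(sum(vals) / len(tumoral))
        return np.array(out)

    def scale(x):
        if x.max() == x.min():
            return np.zeros_like(x)
        return (x - x.min()) / (x.max() - x.min())

    c1 = comp(model.dist_pmbec)
    c2 = comp(model.dist_embedding)
    return dict(zip(normals, scale(c1) + scale(c2)))


class TestSSim:
    def test_identical_peptide_maximal_both_components(self):
        model = toy_model()
        entropy = np.full(9, 0.5)
        pool = ["AAAAAAAAA", "CCCCCCCCC", "DDDDDDDDD"]
        sims = s_sim("AAAAAAAAA", pool, model, entropy)
        assert sims["AAAAAAAAA"] == pytest.approx(2.0)
        assert sims["DDDDDDDDD"] == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self):
        model = synthetic_substitution_model(3)
        rng = np.random.default_rng(7)
        residues = np.array(RESIDUES)
        for trial in range(5):
            pool = sorted(
                "".join(rng.choice(residues, 9)) for _ in range(10)
            )
            tum = "".join(rng.choice(residues, 9))
            entropy = rng.uniform(0, 1, 9)
            got = s_sim(tum, pool, model, entropy)
            want = oracle_s_sim(tum, pool, model, entropy)
            for p in pool:
                assert got[p] == pytest.approx(want[p], abs=1e-12)

    def test_symmetric_in_peptide_roles(self):
        from scanact.pstract import _sim_component

        model = synthetic_substitution_model(3)
        entropy = np.full(9, 0.3)
        rng = np.random.default_rng(9)
        residues = np.array(RESIDUES)
        for _ in range(10):
            pt = "".join(rng.choice(residues, 9))
            pn = "".join(rng.choice(residues, 9))
            for dist in (model.dist_pmbec, model.dist_embedding):
                assert _sim_component(pt, pn, entropy, dist) == pytest.approx(
                    _sim_component(pn, pt, entropy, dist)
                )

    def test_strictly_decreasing_in_distance(self):
        model = toy_model()
        entropy = np.zeros(9)
        sims = s_sim("AAAAAAAAA", ["CAAAAAAAA", "DAAAAAAAA", "AAAAAAAAA"], model, entropy)
        # C is closer to A than D in both components
        assert sims["AAAAAAAAA"] > sims["CAAAAAAAA"] > sims["DAAAAAAAA"]

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            s_sim("AAAAAAAAA", [], toy_model(), np.zeros(9))

    def test_length_mismatch_skipped(self):
        model = toy_model()
        with pytest.raises(ValueError, match="matching length"):
            s_sim("AAAAAAAAA", ["AAAAAAAAAA"], model, np.zeros(9))


def test_diagonal_contribution_maximal_in_synthetic_model():
    """At any position, pairing a residue with itself contributes at
    least as much similarity as pairing with any other residue."""
    model = synthetic_substitution_model(0)
    for a in RESIDUES:
        d_self = model.dist_pmbec(a, a)
        assert d_self == pytest.approx(0.0)
        for b in RESIDUES:
            assert model.dist_pmbec(a, b) >= d_self


class TestSCR:
    def _panel(self):
        return ExpressionPanel(
            pd.DataFrame(
                {"t0": [1.0, 0.0], "t1": [0.5, -1.0]}, index=["P1", "P2"]
            ),
            unit="zscore",
        )

    def _record(self, parent="P1", source="observed", p=0.5):
        return pd.Series(
            {"parent": parent, "source": source, "presentation_score": p}
        )

    def test_observed_arithmetic(self):
        v = s_cr(self._record(), self._panel())
        assert v["t0"] == pytest.approx((0.5 + 0.5) * 1.0 * 1.25)

    def test_predicted_no_boost(self):
        v = s_cr(self._record(source="predicted"), self._panel())
        assert v["t0"] == pytest.approx(1.0)

    def test_zero_expression_zeroes_score(self):
        v = s_cr(self._record(parent="P2"), self._panel())
        assert v["t0"] == 0.0

    def test_missing_parent_skipped(self):
        with pytest.warns(UserWarning, match="absent"):
            assert s_cr(self._record(parent="nope"), self._panel()) is None


class TestProfile:
    def _panel(self):
        return ExpressionPanel(
            pd.DataFrame({"t0": [1.0, 2.0], "t1": [2.0, 1.0]}, index=["P1", "P2"]),
            unit="zscore",
        )

    def test_no_crossreactive_peptides_floor_and_flag(self):
        prof = cr_profile("x", pd.DataFrame([]), self._panel())
        assert prof.no_crossreactive
        assert (prof.scores == 0).all()

    def test_two_records_elementwise_max(self):
        recs = pd.DataFrame(
            [
                {"parent": "P1", "source": "predicted", "presentation_score": 0.5},
                {"parent": "P2", "source": "predicted", "presentation_score": 0.5},
            ]
        )
        prof = cr_profile("x", recs, self._panel())
        assert prof.scores["t0"] == pytest.approx(2.0)
        assert prof.scores["t1"] == pytest.approx(2.0)


class TestSCRDiff:
    def _sigma_one_profiles(self, tissues):
        base = pd.Series(0.0, index=tissues)
        return [base, base + 1.0, base + 2.0]  # per-tissue SD exactly 1

    def test_self_comparison_zero_and_acceptable(self):
        tissues = [f"t{i}" for i in range(5)]
        ref = pd.Series(np.arange(5.0), index=tissues)
        val, ok = s_cr_diff(ref, ref, self._sigma_one_profiles(tissues))
        assert val == 0.0 and ok

    def test_positive_excursion_weighs_alpha(self):
        tissues = [f"t{i}" for i in range(4)]
        ref = pd.Series(0.0, index=tissues)
        prof = ref.copy()
        prof["t0"] = 1.0  # exactly +sigma
        val, ok = s_cr_diff(prof, ref, self._sigma_one_profiles(tissues))
        assert val == pytest.approx(2.0 / 4.0)
        assert not ok

    def test_negative_excursion_unpenalized(self):
        tissues = [f"t{i}" for i in range(4)]
        ref = pd.Series(0.0, index=tissues)
        prof = ref.copy()
        prof["t0"] = -1.0
        val, ok = s_cr_diff(prof, ref, self._sigma_one_profiles(tissues))
        assert val == pytest.approx(-1.0 / 4.0)
        assert ok

    def test_asymmetry_factor_is_exactly_alpha(self):
        tissues = [f"t{i}" for i in range(6)]
        ref = pd.Series(0.0, index=tissues)
        up, down = ref.copy(), ref.copy()
        up["t2"], down["t2"] = 0.7, -0.7
        profs = self._sigma_one_profiles(tissues)
        v_up, _ = s_cr_diff(up, ref, profs)
        v_down, _ = s_cr_diff(down, ref, profs)
        assert v_up == pytest.approx(-2.0 * v_down)

    def test_zero_variance_tissues_excluded_with_warning(self):
        tissues = ["t0", "t1"]
        ref = pd.Series(0.0, index=tissues)
        prof = pd.Series([1.0, 0.0], index=tissues)
        flat = pd.Series([0.0, 5.0], index=tissues)
        profs = [flat, flat + pd.Series([0.0, 1.0], index=tissues)]
        with pytest.warns(UserWarning, match="zero"):
            val, _ = s_cr_diff(prof, ref, profs)
        # only t1 has variance; its delta is 0
        assert val == 0.0

    def test_reference_missing_tissue_errors(self):
        tissues = ["t0", "t1"]
        prof = pd.Series(0.0, index=tissues)
        ref = pd.Series({"t0": 0.0})
        with pytest.raises(ValueError, match="missing"):
            s_cr_diff(prof, ref, self._sigma_one_profiles(tissues))
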