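"""AIC ranking, candidate sets, published-table arithmetic, model averaging."""

import numpy as np
import pandas as pd
import pytest

from occucam import datasets
from occucam.model_selection import (
    aic,
    build_candidate_set,
    full_candidate_set,
    model_average,
    rank_models,
)
from occucam.occupancy_models import ModelSpec, fit


class TestAic:
    @pytest.mark.parametrize(
        "neg2ll, k, expected",
        [(1970.34, 8, 1986.34), (1459.48, 7, 1473.48), (0.0, 0, 0.0)],
    )
    def test_published_and_degenerate_values(self, neg2ll, k, expected):
        assert aic(neg2ll, k) == pytest.approx(expected)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            aic(100.0, -1)


class TestRankModels:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["label", "neg2LL", "K"])

    def test_single_model(self):
        out = rank_models(self.table([("m1", 100.0, 3)]))
        assert out.loc[0, "dAIC"] == 0.0
        assert out.loc[0, "weight"] == pytest.approx(1.0)

    def test_two_model_weights_closed_form(self):
        out = rank_models(self.table([("m1", 100.0, 3), ("m2", 102.0, 3)]))
        w = np.exp(-1) / (1 + np.exp(-1))
        assert out.loc[0, "weight"] == pytest.approx(1 - w, abs=1e-4)
        assert out.loc[1, "weight"] == pytest.approx(w, abs=1e-4)

    def test_weights_sum_to_one_and_shift_invariant(self):
        rng = np.random.default_rng(0)
        rows = [(f"m{i}", float(rng.uniform(500, 600)), int(rng.integers(3, 10)))
                for i in range(8)]
        out = rank_models(self.table(rows))
        assert out["weight"].sum() == pytest.approx(1.0)
        shifted = [(lbl, n + 40.0, k) for lbl, n, k in rows]  # +40 on every AIC
        out2 = rank_models(self.table(shifted))
        assert np.allclose(
            out["weight"].to_numpy(), out2["weight"].to_numpy()
        )
        assert np.allclose(out["dAIC"], out2["dAIC"])

    def test_published_second_ranked_delta(self):
        # second-ranked vs top solar model recomputed from printed (-2LL, K)
        out = rank_models(
            self.table([("top", 1459.48, 7), ("second", 1458.96, 8)])
        )
        assert out.loc[1, "dAIC"] == pytest.approx(1.48)

    def test_mismatched_data_shapes_rejected(self, study_fixture):
        from occucam.detection_data import subset_seasons

        fx = study_fixture
        f1 = fit(ModelSpec("multiseason"), fx.rusa, n_starts=1, seed=0)
        f2 = fit(
            ModelSpec("multiseason"), subset_seasons(fx.rusa, [0, 1]),
            n_starts=1, seed=0,
        )
        with pytest.raises(ValueError, match="same data"):
            rank_models([f1, f2])


class TestCandidateSets:
    def test_group_counts(self):
        assert len(build_candidate_set("multiseason", "solar")) == 25
        assert len(build_candidate_set("multiseason", "soil")) == 25
        assert len(build_candidate_set("multiseason", "plant")) == 9
        assert len(build_candidate_set("multistate")) == 12
        assert len(full_candidate_set("multiseason")) == 59
        assert len(full_candidate_set("twospecies")) == 59

    def test_factor_present_in_every_spec(self):
        for spec in full_candidate_set("multiseason"):
            assert "Season" in spec.label.split(" p(")[0]
            assert "Season" in spec.label.split(" p(")[1]

    def test_multistate_grid_is_full_cross(self):
        combos = {
            (s.r_mode, s.det_state, s.delta_mode)
            for s in build_candidate_set("multistate")
        }
        assert len(combos) == 12

    def test_each_covariate_contributes_eight_models(self):
        solar = build_candidate_set("multiseason", "solar")
        per_cov = pd.Series([s.covariate for s in solar if s.covariate]).value_counts()
        assert per_cov.to_dict() == {"Direct": 8, "Diffuse": 8, "Total": 8}

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="covariate group"):
            build_candidate_set("multiseason", "climate")


class TestPublishedTableConsistency:
    """Printed (-2LL, K) pairs reproduce printed dAIC at 2-decimal rounding."""

    def collect(self):
        blocks = []
        for group, block in datasets.MULTISEASON.items():
            blocks.append((f"multiseason/{group}", block))
        blocks.append(("multistate", datasets.MULTISTATE))
        for group, block in datasets.TWOSPECIES.items():
            blocks.append((f"twospecies/{group}", block))
        return blocks

    def test_all_rows_consistent(self):
        for name, block in self.collect():
            table = block["table"]
            ok = table.get("k_printed_ok", pd.Series(True, index=table.index))
            sub = table[ok]
            recomputed = rank_models(
                sub.assign(label=[f"r{i}" for i in range(len(sub))])[
                    ["label", "neg2LL", "K"]
                ]
            )
            merged = sub.sort_values(["dAIC", "neg2LL"]).reset_index(drop=True)
            # printed -2LL values are rounded to 2 dp, so each recomputed
            # dAIC may be off by at most 0.01 (plus fp noise)
            assert np.all(
                np.abs(recomputed["dAIC"].to_numpy() - merged["dAIC"].to_numpy())
                <= 0.0101
            ), name

    def test_top_aics_reproduced(self):
        for name, block in self.collect():
            top = block["table"].iloc[0]
            assert aic(top["neg2LL"], int(top["K"])) == pytest.approx(
                block["top_aic"], abs=1e-9
            ), name


@pytest.fixture(scope="module")
def fits(study_fixture):
    specs = [
        ModelSpec("multiseason"),
        ModelSpec("multiseason", covariate="Direct", occ_mode="additive",
                  det_mode="additive"),
        ModelSpec("multiseason", covariate="Total", occ_mode="additive",
                  det_mode="additive"),
    ]
    return [
        fit(s, study_fixture.rusa, study_fixture.covariates, n_starts=2, seed=0)
        for s in specs
    ]


class TestModelAverage:
    def test_single_model_average_is_identity(self, fits, study_fixture):
        from occucam.occupancy_models import predict_probabilities

        grid = np.linspace(0.2, 3.0, 5)
        avg = model_average(
            fits[1:2], "Direct", grid, "winter", "occupancy",
            covariates=study_fixture.covariates,
        )
        direct = predict_probabilities(fits[1], grid, "winter", "occupancy")
        assert np.allclose(avg.probability, direct["probability"])
        assert np.allclose(avg.se, direct["se"])

    def test_probability_scale_mixture(self, fits, study_fixture):
        grid = np.array([1.0])
        avg = model_average(
            fits, "Direct", grid, "winter", "occupancy",
            covariates=study_fixture.covariates,
        )
        assert 0.0 <= avg.probability[0] <= 1.0
        assert avg.weights.sum() == pytest.approx(1.0)

    def test_unconditional_se_dominates_weighted_mean_se(self, fits, study_fixture):
        grid = np.linspace(0.2, 3.0, 4)
        avg = model_average(
            fits, "Direct", grid, "winter", "occupancy",
            covariates=study_fixture.covariates,
        )
        # the between-model variance term can only inflate the SE
        from occucam.occupancy_models import predict_probabilities

        per_model_se = []
        for f in fits:
            if f.spec.covariate == "Direct":
                se = predict_probabilities(f, grid, "winter", "occupancy")["se"]
            elif f.spec.covariate == "Total":
                med = study_fixture.covariates.data["diffuse_winter"].median()
                se = predict_probabilities(f, grid + med, "winter", "occupancy")["se"]
            else:
                se = np.full(
                    len(grid), predict_probabilities(f, None, "winter", "occupancy")["se"]
                )
            per_model_se.append(np.atleast_1d(se))
        w = avg.weights
        labels = [f.label for f in fits]
        mean_se = sum(w[lbl] * s for lbl, s in zip(labels, per_model_se))
        assert np.all(avg.se >= mean_se - 1e-12)

    def test_total_solar_grid_respects_sum_constraint(self, fits, study_fixture):
        # averaging against a Direct grid: the Total-solar model must be
        # evaluated at Total = Direct + median(Diffuse), not at a constant
        grid = np.array([0.5, 2.5])
        avg = model_average(
            fits, "Direct", grid, "winter", "occupancy",
            covariates=study_fixture.covariates,
        )
        total_fit = fits[2]
        from occucam.occupancy_models import predict_probabilities

        med_diffuse = study_fixture.covariates.data["diffuse_winter"].median()
        expected = predict_probabilities(
            total_fit, grid + med_diffuse, "winter", "occupancy"
        )["probability"]
        constant = predict_probabilities(
            total_fit,
            np.full(2, study_fixture.covariates.data["total_winter"].median()),
            "winter", "occupancy",
        )["probability"]
        # reconstruct the total-model component from the mixture identity
        others = [f for f in fits if f is not total_fit]
        w = avg.weights
        rest = sum(
            w[f.label] * np.atleast_1d(
                predict_probabilities(
                    f, grid if f.spec.covariate == "Direct" else None,
                    "winter", "occupancy",
                )["probability"]
            )
            for f in others
        )
        component = (avg.probability - rest) / w[total_fit.label]
        assert np.allclose(component, expected, atol=1e-10)
        assert not np.allclose(component, constant)
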