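"""Claims ETL: child filter, refusal coding, quarterly aggregation."""

import datetime as dt
import re

import numpy as np
import pytest

from vaxhes import (aggregate_quarterly, filter_child_claims,
                    filter_zip_population, flag_refusal, normalize_features,
                    pca_transform, simulate_claims)
from vaxhes.claims import ClaimRecord

from conftest import make_claim


class TestFilterChildClaims:
    def test_age_six_inclusive(self):
        records = [make_claim(age=a) for a in (3, 6, 7)]
        kept = filter_child_claims(records, max_age=6)
        assert [r.age_years for r in kept] == [3, 6]

    def test_empty(self):
        assert filter_child_claims([]) == []

    def test_matches_loop_oracle(self, rng):
        records = [make_claim(person=f"p{i}", age=int(a))
                   for i, a in enumerate(rng.integers(0, 15, size=100))]
        kept = filter_child_claims(records, max_age=6)
        oracle = [r for r in records if r.age_years <= 6]
        assert kept == oracle


class TestFlagRefusal:
    @pytest.mark.parametrize("code,expected", [
        ("Z28.82", True), ("Z28", True), ("z28.21", True),
        ("J45.909", False), ("Z23", False), ("A00", False),
    ])
    def test_z28_family(self, code, expected):
        assert flag_refusal(make_claim(dx=code)) is expected

    def test_refusal_flag_wins(self):
        rec = ClaimRecord(person_key="p", incurred_date=dt.date(2020, 1, 1),
                          zip="22001", age_years=2, refusal=True)
        assert flag_refusal(rec) is True

    def test_missing_both_fields_errors(self):
        rec = ClaimRecord(person_key="p", incurred_date=dt.date(2020, 1, 1),
                          zip="22001", age_years=2)
        with pytest.raises(ValueError):
            flag_refusal(rec)

    def test_matches_regex_oracle(self, rng):
        codes = ["Z28.0", "Z28.21", "Z28.9", "Z29.1", "Z2", "J06.9",
                 "Z280", "A28.1", "z28.82", "Z27.8", "B99", "Z28",
                 "R05", "Z23", "Z28.20", "H66.90", "Z28.89", "Z00.1",
                 "Z281.5", "Z2.8"]
        pat = re.compile(r"^Z28", re.IGNORECASE)
        for code in codes:
            assert flag_refusal(make_claim(dx=code)) == bool(pat.match(code))


class TestAggregateQuarterly:
    def test_hand_count(self):
        records = [
            make_claim(person="a", dx="Z28.1"),
            make_claim(person="a", dx="J06.9"),
            make_claim(person="b", dx="J06.9"),
        ]
        panel = aggregate_quarterly(records)
        assert panel.p[0, 0] == 2
        assert panel.h[0, 0] == 0.5

    def test_unique_child_semantics(self):
        # two Z28 claims for the same child count once in the numerator
        records = [
            make_claim(person="a", dx="Z28.1"),
            make_claim(person="a", dx="Z28.9"),
            make_claim(person="b", dx="J06.9"),
        ]
        panel = aggregate_quarterly(records)
        assert panel.h[0, 0] == 0.5

    def test_permutation_invariant(self, rng):
        records = [make_claim(person=f"p{i % 17}",
                              zip_=f"2200{i % 3}",
                              date=dt.date(2020, 1 + (i % 12), 1),
                              dx="Z28.0" if i % 5 == 0 else "J06.9")
                   for i in range(60)]
        p1 = aggregate_quarterly(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        p2 = aggregate_quarterly(shuffled)
        assert p1.zips == p2.zips and p1.timesteps == p2.timesteps
        np.testing.assert_array_equal(p1.p, p2.p)
        np.testing.assert_array_equal(p1.h, p2.h)
        np.testing.assert_array_equal(p1.nc, p2.nc)

    def test_matches_groupby_oracle(self, rng):
        # independent oracle: dictionary-of-sets accumulation
        records = []
        for i in range(500):
            records.append(make_claim(
                person=f"p{rng.integers(0, 80)}",
                zip_=f"220{rng.integers(0, 4):02d}",
                date=dt.date(2020, int(rng.integers(1, 13)), 15),
                dx="Z28.0" if rng.random() < 0.2 else "J06.9"))
        panel = aggregate_quarterly(records)
        seen: dict = {}
        refusing: dict = {}
        for r in records:
            q = f"{r.incurred_date.year}Q{(r.incurred_date.month - 1) // 3 + 1}"
            seen.setdefault((r.zip, q), set()).add(r.person_key)
            if r.dx_code.startswith("Z28"):
                refusing.setdefault((r.zip, q), set()).add(r.person_key)
        for (z, q), persons in seen.items():
            i, t = panel.zips.index(z), panel.timesteps.index(q)
            assert panel.p[i, t] == len(persons)
            assert panel.h[i, t] == pytest.approx(
                len(refusing.get((z, q), set())) / len(persons))

    def test_zero_cells_masked(self):
        records = [make_claim(zip_="22001")]
        panel = aggregate_quarterly(records, zips_keep={"22001", "22002"})
        i = panel.zips.index("22002")
        assert panel.p[i, 0] == 0 and panel.h[i, 0] == 0
        assert not panel.mask[i, 0]

    def test_no_records_errors(self):
        with pytest.raises(ValueError):
            aggregate_quarterly([], zips_keep={"22001"})


class TestFilterZipPopulation:
    def test_threshold_strict(self, small_study):
        panel = small_study["panel"]
        pops = {z: 5000 for z in panel.zips}
        pops[panel.zips[0]] = 900
        pops[panel.zips[1]] = 1000       # boundary: not strictly greater
        kept = filter_zip_population(panel, pops)
        assert panel.zips[0] not in kept.zips
        assert panel.zips[1] not in kept.zips
        assert len(kept.zips) == len(panel.zips) - 2

    def test_all_above_unchanged(self, small_study):
        panel = small_study["panel"]
        kept = filter_zip_population(panel, {z: 2000 for z in panel.zips})
        assert kept.zips == panel.zips

    def test_missing_population_errors(self, small_study):
        panel = small_study["panel"]
        with pytest.raises(ValueError):
            filter_zip_population(panel, {panel.zips[0]: 5000})

    def test_matches_loop_oracle(self, small_study, rng):
        panel = small_study["panel"]
        pops = {z: int(rng.integers(100, 5000)) for z in panel.zips}
        kept = filter_zip_population(panel, pops)
        assert kept.zips == [z for z in panel.zips if pops[z] > 1000]


class TestNormalizeFeatures:
    def test_simple_column(self, small_study):
        panel = small_study["panel"]
        norm = normalize_features(panel)
        assert norm.nc.min() >= 0 and norm.nc.max() <= 1
        # each non-constant column spans exactly [0, 1] within a timestep
        for k in range(panel.n_features):
            for t in range(panel.n_timesteps):
                col = norm.nc[:, k, t]
                raw = panel.nc[:, k, t]
                if raw.max() > raw.min():
                    assert col.min() == 0 and col.max() == 1

    def test_constant_column_maps_to_zero(self, small_study):
        panel = small_study["panel"]
        p2 = panel.subset_zips(panel.zips[:3])
        p2.nc[:, 0, :] = 5.0
        norm = normalize_features(p2)
        assert np.all(norm.nc[:, 0, :] == 0)

    def test_h_untouched_by_default(self, small_study):
        norm = normalize_features(small_study["panel"])
        np.testing.assert_array_equal(norm.h, small_study["panel"].h)

    def test_h_normalized_when_asked(self, small_study):
        norm = normalize_features(small_study["panel"], normalize_h=True)
        assert norm.h.max() <= 1 and norm.h.min() >= 0
        for t in range(norm.n_timesteps):
            if np.ptp(small_study["panel"].h[:, t]) > 0:
                assert norm.h[:, t].max() == pytest.approx(1)

    def test_idempotent(self, small_study):
        once = normalize_features(small_study["panel"])
        twice = normalize_features(once)
        np.testing.assert_allclose(once.nc, twice.nc, atol=1e-12)


class TestPcaTransform:
    def test_full_basis_reconstruction(self, small_study):
        panel = normalize_features(small_study["panel"])
        X = panel.n_features
        out = pca_transform(panel, X)
        evr = out.norm_constants["pca_explained_variance_ratio"]
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)
        assert out.n_features == X

    def test_rank_one_single_component(self):
        from vaxhes.panel import NodePanel
        rng = np.random.default_rng(3)
        base = rng.random((10, 1, 4))
        nc = np.concatenate([base, 2 * base, -base], axis=1)
        panel = NodePanel([f"z{i}" for i in range(10)],
                          ["2020Q1", "2020Q2", "2020Q3", "2020Q4"],
                          nc, np.zeros((10, 4)), np.ones((10, 4), dtype=int),
                          ["a", "b", "c"])
        out = pca_transform(panel, 1)
        evr = out.norm_constants["pca_explained_variance_ratio"]
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle(self, small_study):
        panel = normalize_features(small_study["panel"])
        out = pca_transform(panel, 3)
        flat = panel.nc.transpose(0, 2, 1).reshape(-1, panel.n_features)
        centered = flat - flat.mean(axis=0)
        cov = centered.T @ centered / (flat.shape[0] - 1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        evr = out.norm_constants["pca_explained_variance_ratio"]
        np.testing.assert_allclose(evr, eigvals[:3] / eigvals.sum(),
                                   atol=1e-10)

    def test_too_many_components_errors(self, small_study):
        with pytest.raises(ValueError):
            pca_transform(small_study["panel"],
                          small_study["panel"].n_features + 1)


class TestRoundTrip:
    def test_claims_etl_reproduces_panel(self, small_study):
        """Synthetic claims aggregated by the ETL give back p and h exactly."""
        panel, truth, cfg = (small_study["panel"], small_study["truth"],
                             small_study["cfg"])
        claims = simulate_claims(panel, truth, cfg)
        rebuilt = aggregate_quarterly(
            filter_child_claims(claims), zips_keep=set(panel.zips),
            timesteps=list(panel.timesteps))
        assert rebuilt.zips == panel.zips
        np.testing.assert_array_equal(rebuilt.p, panel.p)
        np.testing.assert_array_equal(rebuilt.h, panel.h)
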