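"""PDB parsing, filtering levels, histograms, confinement and IPH."""

import numpy as np
import pandas as pd
import pytest

from turntilt import (
    DEFAULT_PARAMS,
    Conformation,
    FixtureSpec,
    HarmonicModel,
    TransitionStats,
    build_backbone,
    chain_to_pdb,
    confinement,
    extract_transitions,
    filter_level,
    iph_exact_targets,
    iph_table,
    make_helix_pdb,
    predictability_fraction,
    read_structures,
    transition_means,
)


# ---------------------------------------------------------------------------
# parsing


class TestReadStructures:
    def test_single_helix_yields_n_minus_1_transitions(self, tmp_path):
        spec = FixtureSpec(targets={("A", "A"): (-63.0, -43.0)},
                           samples_per_transition=29, sigma_rho=0.0,
                           sigma_theta=0.0, seed=3)
        paths, _ = make_helix_pdb(spec, tmp_path)
        chains = read_structures(paths)
        assert len(chains) == 1 and len(chains[0]) == 30
        samples = extract_transitions(chains)
        assert len(samples) == 29

    def test_chain_break_omits_transition(self, tmp_path):
        chain = build_backbone(DEFAULT_PARAMS, Conformation(-60.0, -45.0))
        chain.N[15:] += 50.0   # translate the tail: C(14)-N(15) >> 2 A
        chain.CA[15:] += 50.0
        chain.C[15:] += 50.0
        chain.O[15:] += 50.0
        text, _ = chain_to_pdb(chain)
        (tmp_path / "broken.pdb").write_text(text + "END\n")
        samples = extract_transitions(read_structures([tmp_path / "broken.pdb"]))
        assert len(samples) == 28    # transition across the break dropped

    def test_multi_model_uses_first_model_only(self, tmp_path):
        chain = build_backbone(DEFAULT_PARAMS, Conformation(-60.0, -45.0))
        text, _ = chain_to_pdb(chain)
        moved, _ = chain_to_pdb(chain.transformed(np.eye(3), np.array([99.0, 0, 0])))
        content = "MODEL        1\n" + text + "ENDMDL\n" \
            + "MODEL        2\n" + moved + "ENDMDL\nEND\n"
        (tmp_path / "nmr.pdb").write_text(content)
        (rec,) = read_structures([tmp_path / "nmr.pdb"])
        assert len(rec) == 30
        np.testing.assert_allclose(rec.atoms["CA"][0], chain.CA[0], atol=1e-3)

    def test_malformed_file_skipped_with_warning(self, tmp_path):
        (tmp_path / "junk.pdb").write_text("HELIX  bad line\nATOM nonsense\n")
        with pytest.warns(UserWarning):
            chains = read_structures([tmp_path / "junk.pdb"])
        assert chains == []


# ---------------------------------------------------------------------------
# filtering


class TestFilterLevel:
    @pytest.mark.parametrize("phi,psi,in_helix,score,expected", [
        (-60.0, -45.0, True, 0.7, 3),
        (-60.0, -45.0, True, 0.2, 2),
        (-60.0, -45.0, True, 0.001, 1),
        (-60.0, -45.0, False, 0.9, 0),
        (-110.0, -45.0, True, 0.9, -1),   # phi outside the window
        (-60.0, 10.0, True, 0.9, -1),     # psi outside the window
    ])
    def test_level_assignment(self, phi, psi, in_helix, score, expected):
        assert filter_level(phi, psi, in_helix, score) == expected

    def test_decoys_fail_level_zero(self, tmp_path):
        spec = FixtureSpec(targets={("A", "L"): (-63.0, -43.0),
                                    ("L", "A"): (-63.0, -43.0),
                                    ("A", "A"): (-63.0, -43.0),
                                    ("L", "L"): (-63.0, -43.0)},
                           samples_per_transition=14, sigma_rho=0.0,
                           sigma_theta=0.0, seed=5, decoy_fraction=0.5)
        paths, truth = make_helix_pdb(spec, tmp_path)
        samples = extract_transitions(read_structures(paths))
        decoy = samples[samples["level"] < 0]
        assert len(decoy) > 0
        assert len(samples[samples["level"] >= 0]) == len(truth)

    def test_level_counts_nest(self, noisy_samples):
        counts = [int((noisy_samples["level"] >= lvl).sum()) for lvl in range(4)]
        assert counts[0] >= counts[1] >= counts[2] >= counts[3] > 0


# ---------------------------------------------------------------------------
# histograms


class TestTransitionStats:
    def test_accumulate_counts(self):
        stats = TransitionStats()
        stats.accumulate("A", "L", -63.0, -43.0, level=2)
        stats.accumulate("A", "L", -63.0, -43.0, level=0)
        # level-2 sample feeds levels 0..2; level-0 sample only level 0
        assert stats.counts[("A", "L", 0)].sum() == 2
        assert stats.counts[("A", "L", 1)].sum() == 1
        assert stats.counts[("A", "L", 2)].sum() == 1
        assert ("A", "L", 3) not in stats.counts
        stats.accumulate("A", "L", -63.0, -43.0, level=-1)  # rejected sample
        assert stats.counts[("A", "L", 0)].sum() == 2

    def test_single_sample_normalises_to_one(self):
        stats = TransitionStats()
        stats.accumulate("A", "A", -63.0, -43.0, level=0)
        stats.compress_and_normalize()
        h = stats.counts[("A", "A", 0)]
        assert h.sum() == pytest.approx(1.0)
        assert h.max() == pytest.approx(1.0)

    def test_equal_log_counts_share_weight(self):
        stats = TransitionStats()
        h = stats._hist(("A", "A", 0))
        h[3, 3] = np.e - 1
        h[7, 7] = np.e - 1
        stats.compress_and_normalize()
        h = stats.counts[("A", "A", 0)]
        assert h[3, 3] == pytest.approx(0.5) and h[7, 7] == pytest.approx(0.5)

    def test_compression_preserves_bin_ordering(self, rng):
        stats = TransitionStats()
        h = stats._hist(("A", "A", 0))
        h += rng.integers(0, 50, size=h.shape).astype(float)
        order_before = np.argsort(h.ravel())
        stats.compress_and_normalize()
        order_after = np.argsort(stats.counts[("A", "A", 0)].ravel())
        np.testing.assert_array_equal(order_before, order_after)

    def test_all_zero_histogram_flagged(self):
        stats = TransitionStats()
        stats._hist(("G", "G", 0))
        with pytest.warns(UserWarning):
            stats.compress_and_normalize()


# ---------------------------------------------------------------------------
# means, confinement, IPH


@pytest.fixture(scope="module")
def noisy_fixture(tmp_path_factory):
    """Seeded noisy fixture over a 3-letter alphabet, with ground truth."""
    from turntilt import default_transform
    out = tmp_path_factory.mktemp("noisy")
    spec = FixtureSpec(targets=iph_exact_targets("ALG"),
                       samples_per_transition=150,
                       sigma_rho=0.1, sigma_theta=2.0, seed=11)
    paths, truth = make_helix_pdb(spec, out)
    chains = read_structures(paths)
    samples = extract_transitions(chains, default_transform())
    return spec, truth, samples


@pytest.fixture(scope="module")
def noisy_samples(noisy_fixture):
    return noisy_fixture[2]


class TestTransitionMeans:
    def test_zero_noise_mean_is_exact(self, tmp_path, transform):
        spec = FixtureSpec(targets={("A", "A"): (-63.0, -43.0)},
                           samples_per_transition=29, sigma_rho=0.0,
                           sigma_theta=0.0, seed=1)
        paths, _ = make_helix_pdb(spec, tmp_path)
        samples = extract_transitions(read_structures(paths), transform)
        stats = TransitionStats.from_samples(samples).compress_and_normalize()
        means = transition_means(stats, transform)
        lvl0 = means[(means.src == "A") & (means.dst == "A") & (means.level == 0)]
        assert lvl0["phi"].iloc[0] == pytest.approx(-63.0, abs=1e-9)
        assert lvl0["psi"].iloc[0] == pytest.approx(-43.0, abs=1e-9)

    def test_noisy_means_recover_generator_draws(self, noisy_fixture, transform):
        spec, truth, samples = noisy_fixture
        stats = TransitionStats.from_samples(samples).compress_and_normalize()
        means = transition_means(stats, transform).set_index(["src", "dst", "level"])
        for (x, y), grp in truth.groupby(["src", "dst"]):
            # oracle: the generator's own drawn sample means
            se_phi = grp["phi"].std() / np.sqrt(len(grp))
            se_psi = grp["psi"].std() / np.sqrt(len(grp))
            row = means.loc[(x, y, 0)]
            bin_slack = 1.0   # half the 2-degree histogram bin
            assert abs(row["phi"] - grp["phi"].mean()) < 3 * se_phi + bin_slack
            assert abs(row["psi"] - grp["psi"].mean()) < 3 * se_psi + bin_slack


class TestConfinement:
    @staticmethod
    def _samples(rho, theta):
        return pd.DataFrame({"rho": rho, "theta": theta,
                             "level": np.full(len(rho), 3)})

    def test_isotropic_cloud_matches_median_radius(self, rng):
        K = HarmonicModel().K
        theta = rng.normal(0.0, 5.0, 4000)
        rho = rng.normal(3.6, 5.0 / K, 4000)
        st = confinement(self._samples(rho, theta), K=K, shape="ellipse")
        radius = np.hypot(theta - theta.mean(), K * (rho - rho.mean()))
        expected = np.quantile(radius, 0.5)
        row = st.per_level.set_index("level").loc[3]
        assert row["d_theta"] == pytest.approx(expected, rel=1e-9)
        assert row["d_rho"] == pytest.approx(expected / K, rel=1e-9)

    def test_point_mass_has_zero_width(self):
        st = confinement(self._samples(np.full(5, 3.6), np.full(5, 9.0)))
        assert (st.per_level["d_theta"] == 0).all()

    def test_duplicating_samples_leaves_widths_unchanged(self, rng):
        theta = rng.normal(0, 3, 400)
        rho = rng.normal(3.6, 0.2, 400)
        s1 = confinement(self._samples(rho, theta))
        s2 = confinement(self._samples(np.tile(rho, 2), np.tile(theta, 2)))
        assert s1.d_theta_mean == pytest.approx(s2.d_theta_mean, rel=1e-9)

    def test_box_contour_is_chebyshev(self, rng):
        K = HarmonicModel().K
        theta = rng.normal(0, 5.0, 2000)
        rho = rng.normal(3.6, 5.0 / K, 2000)
        st = confinement(self._samples(rho, theta), K=K, shape="box")
        radius = np.maximum(np.abs(theta - theta.mean()),
                            K * np.abs(rho - rho.mean()))
        row = st.per_level.set_index("level").loc[3]
        assert row["d_theta"] == pytest.approx(np.quantile(radius, 0.5), rel=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            confinement(self._samples(np.array([3.6]), np.array([9.0])))

    def test_invalid_shape_rejected(self, rng):
        with pytest.raises(ValueError):
            confinement(self._samples(rng.normal(3.6, 0.1, 10),
                                      rng.normal(9, 1, 10)), shape="diamond")


def _means_frame(entries, level=1):
    rows = [{"src": x, "dst": y, "level": level, "phi": 0.0, "psi": 0.0,
             "rho": r, "theta": t, "weight": 1.0} for (x, y, r, t) in entries]
    return pd.DataFrame(rows)


class TestIphTable:
    def test_exact_average_gives_zero(self):
        means = _means_frame([("A", "A", 3.60, 10.0), ("L", "L", 3.70, 14.0),
                              ("A", "L", 3.65, 12.0), ("L", "A", 3.65, 12.0)])
        table = iph_table(means)
        assert table.loc["A", "L"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["A", "A"] == pytest.approx(0.0, abs=1e-12)

    def test_one_degree_theta_offset_costs_one_eu(self):
        means = _means_frame([("A", "A", 3.60, 10.0), ("L", "L", 3.60, 14.0),
                              ("A", "L", 3.60, 11.0)])   # predicted theta = 12
        table = iph_table(means)
        assert table.loc["A", "L"] == pytest.approx(1.0)

    def test_asymmetry_is_representable(self):
        means = _means_frame([("A", "A", 3.60, 10.0), ("L", "L", 3.60, 14.0),
                              ("A", "L", 3.60, 11.0), ("L", "A", 3.60, 12.5)])
        table = iph_table(means)
        assert table.loc["A", "L"] != table.loc["L", "A"]

    def test_missing_means_leave_nan(self):
        means = _means_frame([("A", "A", 3.6, 10.0)])
        table = iph_table(means)
        assert np.isnan(table.loc["A", "L"])
        assert table.loc["A", "A"] == 0.0

    def test_offset_rows_dominate_row_means(self, transform):
        # generator places P-transitions far from their homogeneous average:
        # the P row must dominate the table's row means
        entries = []
        for aa, th in [("A", 10.0), ("L", 11.0), ("P", 2.0)]:
            entries.append((aa, aa, 3.6, th))
        for x, y in [("A", "L"), ("L", "A")]:
            entries.append((x, y, 3.6, 10.5))       # exactly the average
        for x in "AL":
            entries.append(("P", x, 3.6, 18.0))     # far off the average
            entries.append((x, "P", 3.6, (10.0 if x == "A" else 11.0) / 2 + 1.0))
        table = iph_table(_means_frame(entries))
        row_means = table.mean(axis=1, skipna=True)
        assert row_means["P"] == row_means.max()
        # oracle: direct harmonic arithmetic on the generator offsets
        assert table.loc["P", "A"] == pytest.approx((18.0 - 6.0) ** 2)


class TestPredictability:
    def test_infinite_tolerance_is_one(self):
        means = _means_frame([("A", "A", 3.6, 10.0), ("L", "L", 3.6, 14.0),
                              ("A", "L", 3.6, 11.0)])
        assert predictability_fraction(iph_table(means), np.inf) == 1.0

    def test_exact_iph_fixture_fully_predictable_at_zero(self, tmp_path, transform):
        spec = FixtureSpec(targets=iph_exact_targets("ALG"),
                           samples_per_transition=29, sigma_rho=0.0,
                           sigma_theta=0.0, seed=2)
        paths, _ = make_helix_pdb(spec, tmp_path)
        samples = extract_transitions(read_structures(paths), transform)
        stats = TransitionStats.from_samples(samples).compress_and_normalize()
        means = transition_means(stats, transform)
        table = iph_table(means, level=1)
        off = table.to_numpy()[~np.eye(20, dtype=bool)]
        assert np.nanmax(off) == pytest.approx(0.0, abs=1e-9)
        # tolerance at float-arithmetic dust: every filled cell is zero
        assert predictability_fraction(table, 1e-9) == 1.0

    def test_threshold_counts_brute_force(self, rng):
        table = pd.DataFrame(rng.uniform(0, 30, size=(20, 20)),
                             index=list("ARNDCQEGHILKMFPSTWYV"),
                             columns=list("ARNDCQEGHILKMFPSTWYV"))
        np.fill_diagonal(table.values, 0.0)
        tol = 10.0
        vals = table.to_numpy()[~np.eye(20, dtype=bool)]
        expected = (vals <= tol).sum() / 380
        assert predictability_fraction(table, tol) == pytest.approx(expected)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            predictability_fraction(pd.DataFrame(np.zeros((2, 2))), -1.0)
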