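"""Synthetic parcellation and cohort generator."""

import numpy as np
import pytest

from covnet import (SynthSpec, make_parcellation, read_cohort_tsv,
                    read_parcellation_tsv, simulate_cohort, symmetric_partition,
                    write_cohort_tsv, write_parcellation_tsv)
from covnet.synth import population_correlation


class TestMakeParcellation:
    def test_smallest_valid_parcellation(self):
        parc = make_parcellation(2, rng_seed=0)
        assert parc.n_regions == 4
        # mirror pairs cross hemispheres: {1<->3, 2<->4} up to labeling
        assert sorted((i + 1, int(parc.mirror[i])) for i in range(2)) == \
            [(1, 3), (2, 4)]

    def test_paper_scale_parcel_count(self):
        parc = make_parcellation(154, rng_seed=3)
        assert parc.n_regions == 308
        parc.validate()

    @pytest.mark.parametrize("n,seed", [(5, 0), (10, 1), (30, 2)])
    def test_structural_invariants(self, n, seed):
        parc = make_parcellation(n, rng_seed=seed)
        parc.validate()  # involution, x-reflection, symmetry, contiguity
        for i in range(parc.n_regions):
            m = parc.mirror_index(i)
            assert parc.hemisphere[i] != parc.hemisphere[m]
            assert np.isclose(parc.centroids[i, 0], -parc.centroids[m, 0])

    def test_rejects_nonpositive_count(self):
        with pytest.raises(ValueError):
            make_parcellation(1, rng_seed=0)

    def test_deterministic(self):
        a = make_parcellation(12, rng_seed=5)
        b = make_parcellation(12, rng_seed=5)
        assert np.array_equal(a.centroids, b.centroids)
        assert a.neighbors == b.neighbors


class TestSimulateCohort:
    def test_common_factor_limit(self, parc20):
        # infinite decay length, no independent noise: one common factor,
        # all inter-regional correlations ~1
        spec = SynthSpec(n_regions=20, n_per_group={"NT": 200},
                         decay_length={"NT": np.inf}, rng_seed=4)
        cohort = simulate_cohort(parc20, spec)
        values = np.vstack([s.values for s in cohort])
        R = np.corrcoef(values, rowvar=False)
        assert R.min() > 0.99

    def test_decay_length_orders_fitted_slopes(self, parc60):
        # the 50 mm group must show the steeper (more negative)
        # correlation-vs-distance regression slope
        from scipy.spatial.distance import pdist, squareform
        spec = SynthSpec(n_regions=60,
                         n_per_group={"A": 200, "B": 200},
                         decay_length={"A": 100.0, "B": 50.0}, rng_seed=9)
        cohort = simulate_cohort(parc60, spec)
        D = squareform(pdist(parc60.centroids))
        iu = np.triu_indices(60, k=1)
        slopes = {}
        for g in ("A", "B"):
            values = np.vstack([s.values for s in cohort if s.group == g])
            r = np.corrcoef(values, rowvar=False)[iu]
            slopes[g] = np.polyfit(D[iu], r, 1)[0]
        assert slopes["B"] < slopes["A"] < 0

    def test_deterministic_given_seed(self, parc20):
        spec = SynthSpec(n_regions=20, n_per_group={"NT": 10},
                         decay_length={"NT": 60.0}, rng_seed=8)
        c1 = simulate_cohort(parc20, spec)
        c2 = simulate_cohort(parc20, spec)
        assert all(np.array_equal(a.values, b.values)
                   for a, b in zip(c1, c2))
        assert [s.subject_id for s in c1] == [s.subject_id for s in c2]

    def test_empirical_correlation_converges_to_population(self, parc20):
        C_pop = population_correlation(parc20, 60.0)
        errs = []
        for n in (50, 400):
            spec = SynthSpec(n_regions=20, n_per_group={"NT": n},
                             decay_length={"NT": 60.0}, rng_seed=13)
            values = np.vstack([s.values for s in simulate_cohort(parc20, spec)])
            R = np.corrcoef(values, rowvar=False)
            errs.append(np.linalg.norm(R - C_pop))
        assert errs[1] < errs[0]

    def test_planted_partition_is_mirror_symmetric_and_boosts(self, parc60):
        template = symmetric_partition(parc60, 4, rng_seed=2)
        for i in range(parc60.n_regions):
            assert template.labels[i] == template.labels[parc60.mirror_index(i)]
        spec = SynthSpec(n_regions=60, n_per_group={"NT": 300},
                         decay_length={"NT": 60.0},
                         planted_partition={"NT": template.labels},
                         module_boost=0.3, rng_seed=5)
        values = np.vstack([s.values for s in simulate_cohort(parc60, spec)])
        R = np.corrcoef(values, rowvar=False)
        same = template.labels[:, None] == template.labels[None, :]
        off = ~np.eye(60, dtype=bool)
        assert R[same & off].mean() > R[~same].mean() + 0.1

    def test_values_positive_and_sized(self, two_group_cohort):
        for s in two_group_cohort:
            assert len(s.values) == 60
            assert np.all(s.values > 0)

    def test_group_sizes_and_site_cycling(self, two_group_cohort):
        groups = {}
        for s in two_group_cohort:
            groups.setdefault(s.group, []).append(s.site)
        assert {g: len(v) for g, v in groups.items()} == {"NT": 40, "ADHD": 40}
        assert set(groups["NT"]) == {"s1", "s2"}

    def test_rejects_bad_spec(self, parc20):
        with pytest.raises(ValueError):
            SynthSpec(n_regions=20, n_per_group={"NT": 2},
                      decay_length={"NT": 60.0}).validate(parc20)
        with pytest.raises(ValueError):
            SynthSpec(n_regions=20, n_per_group={"NT": 5},
                      decay_length={"NT": -1.0}).validate(parc20)
        with pytest.raises(ValueError):
            SynthSpec(n_regions=19, n_per_group={"NT": 5},
                      decay_length={"NT": 60.0}).validate(parc20)


class TestCouplingHeterogeneity:
    def test_zero_heterogeneity_is_pure_decay(self, parc20):
        from covnet.synth import coupling_matrix
        S = coupling_matrix(20, 0.0, 12, rng_seed=1)
        assert np.array_equal(S, np.ones((20, 20)))

    def test_coupled_population_matrix_valid(self, parc20):
        from covnet.synth import coupling_matrix
        S = coupling_matrix(20, 0.7, 12, rng_seed=1)
        assert np.allclose(np.diag(S), 1.0)
        assert np.linalg.eigvalsh(S)[0] > -1e-10
        C = population_correlation(parc20, 60.0, coupling=S)
        assert np.linalg.eigvalsh(C)[0] > 0
        assert np.allclose(np.diag(C), 1.0)
        # heterogeneity must actually spread the couplings
        off = S[np.triu_indices(20, 1)]
        assert off.std() > 0.1


class TestPsdRepair:
    def test_boost_breaking_psd_is_repaired(self, parc20):
        labels = np.tile([1, 2], 10)  # spatially scattered planted modules
        C = population_correlation(parc20, 30.0, labels, module_boost=0.9)
        w = np.linalg.eigvalsh(C)
        assert w[0] > 0
        assert np.allclose(np.diag(C), 1.0)


class TestTsvRoundTrip:
    def test_parcellation(self, parc20, tmp_path):
        path = tmp_path / "parc.tsv"
        write_parcellation_tsv(parc20, path)
        back = read_parcellation_tsv(path)
        assert np.array_equal(back.region_ids, parc20.region_ids)
        assert np.array_equal(back.mirror, parc20.mirror)
        assert np.allclose(back.centroids, parc20.centroids, atol=1e-5)
        assert back.neighbors == parc20.neighbors

    def test_cohort(self, two_group_cohort, tmp_path):
        path = tmp_path / "cohort.tsv"
        write_cohort_tsv(two_group_cohort, path)
        back = read_cohort_tsv(path)
        assert [s.subject_id for s in back] == \
            [s.subject_id for s in two_group_cohort]
        assert all(np.allclose(a.values, b.values, atol=1e-7)
                   for a, b in zip(back, two_group_cohort))
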