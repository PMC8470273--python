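"""Event calculus: minimal counts, metric axioms, explicit event paths."""

import itertools

import numpy as np
import pytest

from karyoevo import (
    EventCount,
    KaryotypeFormula,
    SimulationConfig,
    apply_events,
    combined_event_path,
    count_translocations_fissions,
    evolve_karyotypes,
    inversion_distance,
    parse_formula,
)
from karyoevo.rearrangements import Fission, Inversion, Translocation


class TestTranslocationFissionCounts:
    @pytest.mark.parametrize(
        "a, b, translocations",
        [(60, 52, 4), (52, 42, 5), (52, 46, 3), (52, 48, 2),
         (60, 54, 3), (60, 58, 1), (58, 56, 1), (60, 44, 8)],
    )
    def test_chromosome_number_reductions(self, a, b, translocations):
        assert count_translocations_fissions(a, b) == EventCount(
            translocations=translocations
        )

    def test_single_fission_raises_2n(self):
        assert count_translocations_fissions(58, 60) == EventCount(fissions=1)

    def test_identity(self):
        assert count_translocations_fissions(54, 54) == EventCount()

    @pytest.mark.parametrize("a, b", [(53, 54), (54, 53)])
    def test_odd_rejected(self, a, b):
        with pytest.raises(ValueError, match="even"):
            count_translocations_fissions(a, b)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            count_translocations_fissions(20, 60)
        count_translocations_fissions(20, 28, diploid_range=(10, 40))

    def test_additive_along_monotone_chains(self):
        for a, b, c in [(60, 54, 44), (44, 52, 60), (42, 50, 64)]:
            d = lambda x, y: count_translocations_fissions(x, y).total
            assert d(a, c) == d(a, b) + d(b, c)


def _all_formulae(n_pairs: int):
    for m, sm, st in itertools.product(range(n_pairs + 1), repeat=3):
        t = n_pairs - m - sm - st
        if t >= 0:
            yield KaryotypeFormula({"m": m, "sm": sm, "st": st, "t": t})


class TestInversionDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("24m+2sm+1st", "21m+4sm+2st", 3),   # H. straminea -> H. gussoneana
            ("24m+2sm+1st", "18m+8sm+1st", 6),   # H. straminea -> H. pomatia
            ("24m+2sm+1st", "10m+1sm+16t", 16),  # H. straminea -> H. lucorum
            ("20m+4sm", "16m+6sm+2t", 4),        # T. pyramidata -> T. elegans
        ],
    )
    def test_printed_series(self, a, b, expected):
        assert inversion_distance(parse_formula(a), parse_formula(b)) == expected

    def test_trochoides_half_l1_value(self):
        """T. pyramidata -> T. trochoides under the half-L1 rule.

        Three pairs gain arms and one loses: four class changes, so the
        minimal pericentric-inversion count is 4 (one inversion per pair).
        """
        assert inversion_distance(parse_formula("20m+4sm"), parse_formula("16m+7sm+1t")) == 4

    def test_identity_zero(self):
        f = parse_formula("16m+6sm+2t")
        assert inversion_distance(f, f) == 0

    def test_unequal_pair_numbers_point_to_combined_path(self):
        with pytest.raises(ValueError, match="combined_event_path"):
            inversion_distance(parse_formula("30m"), parse_formula("26m"))

    @pytest.mark.parametrize("n", range(1, 7))
    def test_metric_axioms_exhaustive(self, n):
        """Identity, symmetry and triangle inequality for all formulae, n <= 6."""
        forms = list(_all_formulae(n))
        vecs = np.array([f.as_vector() for f in forms])
        D = np.abs(vecs[:, None, :] - vecs[None, :, :]).sum(axis=2) // 2
        # spot-check the vectorised distance against the public function
        rng = np.random.default_rng(n)
        for i, j in rng.integers(len(forms), size=(10, 2)):
            assert D[i, j] == inversion_distance(forms[i], forms[j])
        assert (np.diag(D) == 0).all()
        assert (D.T == D).all()
        assert ((D == 0) == np.eye(len(forms), dtype=bool)).all()  # zero iff equal
        assert (D[:, :, None] <= D[:, None, :] + D[None, :, :]).all()


class TestEvents:
    def test_translocation_requires_available_pairs(self):
        with pytest.raises(ValueError, match="infeasible"):
            Translocation("st", "st").apply(parse_formula("30m"))

    def test_fission_requires_biarmed(self):
        with pytest.raises(ValueError, match="biarmed"):
            Fission("t").apply(parse_formula("10m+2t"))

    def test_inversion_moves_one_pair(self):
        f = Inversion("m", "t").apply(parse_formula("30m"))
        assert f == parse_formula("29m+1t")


class TestCombinedEventPath:
    def test_equal_n_reduces_to_inversions(self):
        a, b = parse_formula("24m+2sm+1st"), parse_formula("18m+8sm+1st")
        path = combined_event_path(a, b)
        assert len(path) == inversion_distance(a, b)
        assert all(isinstance(e, Inversion) for e in path)

    def test_pure_translocation_path(self):
        path = combined_event_path(parse_formula("30m"), parse_formula("26m"))
        assert len(path) == 4
        assert all(isinstance(e, Translocation) for e in path)

    def test_infeasible_fission_names_blocking_class(self):
        with pytest.raises(ValueError, match="blocking class: t"):
            combined_event_path(parse_formula("1m+10t"), parse_formula("5m+5sm+5st+5t"))

    def test_replay_reproduces_target_on_simulated_pairs(self):
        """Path replay on 1,000 formula pairs produced by the simulator."""
        rng = np.random.default_rng(99)
        checked = 0
        seed_iter = iter(rng.integers(2**31, size=400))
        while checked < 1000:
            sim = evolve_karyotypes(SimulationConfig(n_tips=6, seed=int(next(seed_iter))))
            forms = list(sim.tip_formulae.values()) + [sim.root_formula]
            for a, b in itertools.combinations(forms, 2):
                try:
                    path = combined_event_path(a, b)
                except ValueError:
                    continue  # legitimately infeasible intermediate
                assert apply_events(a, path) == b
                assert len(path) >= abs(a.n_pairs - b.n_pairs)
                checked += 1
        assert checked >= 1000

    def test_lower_bound_on_true_event_count(self):
        """Pairwise minimal counts never exceed the simulated event number."""
        for seed in range(20):
            sim = evolve_karyotypes(SimulationConfig(n_tips=2, seed=seed))
            (ta, tb) = sorted(sim.tip_formulae)
            fa, fb = sim.tip_formulae[ta], sim.tip_formulae[tb]
            true_events = sim.true_event_count
            mincount = count_translocations_fissions(
                fa.diploid_number, fb.diploid_number
            ).total
            if fa.n_pairs == fb.n_pairs:
                mincount = max(mincount, inversion_distance(fa, fb))
            assert mincount <= true_events
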