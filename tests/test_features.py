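"""Feature construction: AFV lookup, distance weighting, point features,
IFV aggregation and dataset assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prank.config import PrankConfig
from prank.features import (
    FeaturizationContext,
    POINT_FEATURE_NAMES,
    aggregate_ifv,
    atomic_neighborhood,
    build_point_dataset,
    compute_afv,
    compute_point_features,
    protrusion_index,
    weight,
)
from prank.structure_io import Atom
from prank.surface import sample_sas_points, solvent_exposed_atoms

from conftest import build_structure


def _atom(resname, name, coords=(0, 0, 0), serial=1, b=20.0):
    return Atom(serial=serial, element=name[0], name=name,
                coords=np.asarray(coords, dtype=float),
                residue_key=("A", serial, "", resname), b_factor=b,
                is_hetero=False)


class TestWeight:
    @pytest.mark.parametrize("d,expected", [(0.0, 1.0), (8.0, 0.0), (4.0, 0.5)])
    def test_endpoints_and_midpoint(self, d, expected):
        assert weight(d) == expected

    @given(st.floats(min_value=0.0, max_value=8.0, allow_nan=False))
    @settings(max_examples=50, derandomize=True)
    def test_symmetry_w_a_plus_w_8_minus_a_is_one(self, a):
        assert weight(a) + weight(8.0 - a) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("d", [-0.1, 8.1])
    def test_domain_violation_raises(self, d):
        with pytest.raises(ValueError):
            weight(d)


class TestAFV:
    def test_ile_hydropathy_component(self, tables):
        afv = compute_afv(_atom("ILE", "CA"), tables)
        i = tables.afv_feature_names.index("res_hydropathy")
        assert afv[i] == 4.5

    def test_same_residue_shares_residue_block(self, tables):
        n_res = len(tables.residue_table.columns)
        a = compute_afv(_atom("SER", "CB"), tables)
        b = compute_afv(_atom("SER", "OG"), tables)
        np.testing.assert_array_equal(a[:n_res], b[:n_res])
        assert not np.array_equal(a[n_res:], b[n_res:])

    def test_unknown_residue_falls_back_to_zeros(self, tables):
        n_res = len(tables.residue_table.columns)
        afv = compute_afv(_atom("XYZ", "QQ"), tables)
        np.testing.assert_array_equal(afv, np.zeros_like(afv))
        assert len(afv) == tables.n_afv
        assert n_res > 0


class TestNeighborhood:
    def test_radius_boundary_inclusive_and_buried_excluded(self):
        st_ = build_structure([[7.9, 0, 0], [8.1, 0, 0], [3.0, 0, 0]])
        exposed = {1, 2}  # declare atom 3 buried
        neigh = atomic_neighborhood([0, 0, 0], exposed, st_, radius=8.0)
        serials = [a.serial for a, _ in neigh]
        assert serials == [1]
        assert neigh[0][1] == pytest.approx(7.9)

    def test_exactly_8_included(self):
        st_ = build_structure([[8.0, 0, 0]])
        neigh = atomic_neighborhood([0, 0, 0], {1}, st_, radius=8.0)
        assert len(neigh) == 1


class TestProtrusion:
    def test_empty_sphere_returns_cap(self):
        st_ = build_structure([[100, 0, 0]])
        assert protrusion_index([0, 0, 0], st_, R=10.0, cap=15.0) == 15.0

    def test_monotone_decreasing_in_density(self):
        rng = np.random.default_rng(0)
        sparse = build_structure(rng.normal(scale=5, size=(20, 3)))
        dense = build_structure(rng.normal(scale=5, size=(200, 3)))
        assert protrusion_index([0, 0, 0], dense) < \
            protrusion_index([0, 0, 0], sparse)

    def test_neighbor_count_matches_brute_force(self, small_corpus, config):
        structure, _ = small_corpus[0]
        rng = np.random.default_rng(1)
        points = rng.normal(scale=12, size=(25, 3))
        v = 20.1
        v_sphere = 4 / 3 * np.pi * config.protrusion_radius**3
        for p in points:
            n = sum(
                np.linalg.norm(a.coords - p) <= config.protrusion_radius
                for a in structure.atoms
            )
            expected = (min((v_sphere - n * v) / (n * v), config.protrusion_cap)
                        if n else config.protrusion_cap)
            assert protrusion_index(p, structure) == pytest.approx(expected)


class TestPointFeatures:
    def test_empty_neighborhood(self, tables, config):
        st_ = build_structure([[100, 0, 0]])
        fv = compute_point_features([0, 0, 0], st_, [], tables, config)
        np.testing.assert_allclose(fv, [0, 0, 0.0, config.protrusion_cap])

    def test_ser_og_counts_as_donor_and_acceptor(self, tables, config):
        st_ = build_structure([[1, 0, 0]], resnames=["SER"], atom_names=["OG"])
        neigh = [(st_.atoms[0], 1.0)]
        fv = compute_point_features([0, 0, 0], st_, neigh, tables, config)
        assert fv[0] == 1 and fv[1] == 1

    def test_mean_bfactor(self, tables, config):
        st_ = build_structure([[1, 0, 0], [2, 0, 0]], b_factors=[10.0, 30.0])
        neigh = [(a, 1.0) for a in st_.atoms]
        fv = compute_point_features([0, 0, 0], st_, neigh, tables, config)
        assert fv[2] == 20.0


class TestAggregation:
    def test_single_neighbor_at_zero_distance_is_identity(self, tables):
        atom = _atom("TRP", "NE1")
        ifv = aggregate_ifv([(atom, 0.0)], tables, np.zeros(4))
        np.testing.assert_allclose(ifv[:tables.n_afv], compute_afv(atom, tables))

    def test_two_midpoint_neighbors_sum_to_one_afv(self, tables):
        atom = _atom("TYR", "OH")
        ifv = aggregate_ifv([(atom, 4.0), (atom, 4.0)], tables, np.zeros(4))
        np.testing.assert_allclose(ifv[:tables.n_afv],
                                   compute_afv(atom, tables), atol=1e-12)

    def test_empty_neighborhood_is_zeros_then_fv(self, tables):
        fv = np.array([1.0, 2.0, 3.0, 4.0])
        ifv = aggregate_ifv([], tables, fv)
        np.testing.assert_array_equal(ifv[:tables.n_afv], 0.0)
        np.testing.assert_array_equal(ifv[tables.n_afv:], fv)

    def test_batch_featurization_matches_naive_per_point_loop(
            self, small_corpus, tables, config):
        """Vectorized IFVs equal the double-loop aggregation to 1e-9."""
        structure, pockets = small_corpus[0]
        sas = sample_sas_points(structure)
        exposed = solvent_exposed_atoms(structure, points=sas)
        ctx = FeaturizationContext(structure, tables, exposed, config)
        rng = np.random.default_rng(2)
        idx = rng.choice(len(sas), size=15, replace=False)
        batch = ctx.featurize(sas.coords[idx])
        for row, i in zip(batch, idx):
            point = sas.coords[i]
            neigh = atomic_neighborhood(point, exposed, structure,
                                        config.neighborhood_radius)
            fv = compute_point_features(point, structure, neigh, tables, config)
            expected = aggregate_ifv(neigh, tables, fv)
            np.testing.assert_allclose(row, expected, atol=1e-9)


def test_ifv_locality_distant_perturbation_is_invisible(tables, config):
    """Moving an atom 20 Å from the probe point leaves its IFV bit-identical."""
    rng = np.random.default_rng(3)
    near = rng.normal(scale=3, size=(15, 3))
    far = np.array([[25.0, 0, 0]])
    point = np.zeros(3)

    def ifv_with(far_coords):
        st_ = build_structure(np.vstack([near, far_coords]))
        exposed = solvent_exposed_atoms(st_)
        ctx = FeaturizationContext(st_, tables, exposed, config)
        return ctx.featurize(point[None, :])[0]

    a = ifv_with(far)
    b = ifv_with(far + [3.0, 2.0, 1.0])   # still > 20 Å from the point
    np.testing.assert_array_equal(a, b)


class TestBuildPointDataset:
    def test_row_count_is_sum_of_inner_points(self, small_corpus, config):
        from prank.surface import label_points, select_inner_points
        structure, pockets = small_corpus[0]
        ds = build_point_dataset([(structure, pockets)], config=config)
        sas = sample_sas_points(structure)
        expected = sum(
            len(select_inner_points(sas, p, structure, config.inner_belt))
            for p in pockets
        )
        assert len(ds) == expected
        assert set(ds.groups) == {structure.id}

    def test_no_ligand_protein_yields_all_negative(self, small_corpus):
        structure, pockets = small_corpus[1]
        stripped = build_structure(
            structure.coords,
            resnames=[a.resname for a in structure.atoms],
            atom_names=[a.name for a in structure.atoms],
            elements=[a.element for a in structure.atoms],
            b_factors=[a.b_factor for a in structure.atoms],
            structure_id="no-lig",
        )
        ds = build_point_dataset([(stripped, pockets)])
        assert (ds.y == 0).all()

    def test_deterministic_rebuild(self, small_corpus):
        a = build_point_dataset(small_corpus[:2])
        b = build_point_dataset(small_corpus[:2])
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)
        assert a.schema_version == b.schema_version

    def test_schema_refuses_to_mix(self, small_dataset, small_model):
        from prank.model import SchemaMismatchError, predict_p1
        with pytest.raises(SchemaMismatchError):
            predict_p1(small_model, small_dataset.X, schema_version="other-schema")

    def test_feature_names_cover_afv_and_point_blocks(self, tables):
        names = tables.feature_names
        assert names[-4:] == list(POINT_FEATURE_NAMES)
        assert len(names) == tables.n_afv + 4
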