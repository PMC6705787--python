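import numpy as np
import pytest

from conftest import make_record
from s1census.conservation import (
    conserved_domain_summary,
    extract_domains,
    interdomain_identity_matrix,
    reference_scan,
    within_position_identity,
)
from s1census.errors import InsufficientDataError, ValidationError
from s1census.records_io import Dataset
from s1census.synthetic_data import (
    SimulationConfig,
    sample_ancestral_domain,
    simulate_dataset,
)


class TestExtractDomains:
    def test_slices_by_boundaries(self):
        rec = make_record("A", sequence="AAACCCGGG", boundaries=((1, 3), (7, 9)))
        doms = extract_domains(rec)
        assert [d.subsequence for d in doms] == ["AAA", "GGG"]
        assert [d.domain_index for d in doms] == [1, 2]

    def test_whole_sequence_domain(self):
        rec = make_record("A", sequence="MKVLQ", boundaries=((1, 5),))
        assert extract_domains(rec)[0].subsequence == "MKVLQ"

    def test_six_domains_in_chain_order(self):
        fam = simulate_dataset(
            SimulationConfig(seed=5, n_records=1,
                             phylum_profile=(("Proteobacteria", 6, 1.0),))
        )
        doms = extract_domains(fam.dataset.records[0])
        assert [d.domain_index for d in doms] == [1, 2, 3, 4, 5, 6]
        assert all(len(d.subsequence) == 70 for d in doms)


def _clone_dataset(n=4, k=3):
    """Records that are exact copies: domains differ across positions but
    not across records."""
    doms = [sample_ancestral_domain(40, seed) for seed in (10, 20, 30)][:k]
    seq = "".join(doms)
    bounds = tuple((1 + 40 * i, 40 * (i + 1)) for i in range(k))
    return Dataset([
        make_record(f"C{i}", sequence=seq, boundaries=bounds) for i in range(n)
    ])


class TestIdentityMatrix:
    def test_clone_diagonal_is_100(self):
        m = interdomain_identity_matrix(_clone_dataset(), 3)
        assert np.allclose(np.diag(m.values), 100.0)
        assert m.values.min() >= 0.0 and m.values.max() <= 100.0

    def test_symmetric(self, small_family):
        m = interdomain_identity_matrix(small_family.dataset, 6)
        assert np.allclose(m.values, m.values.T)
        assert np.array_equal(m.n_pairs, m.n_pairs.T)

    def test_record_permutation_invariant(self, small_family):
        ds = small_family.dataset
        m1 = interdomain_identity_matrix(ds, 6)
        m2 = interdomain_identity_matrix(Dataset(list(reversed(ds.records))), 6)
        assert np.allclose(m1.values, m2.values)

    def test_insufficient_group_raises(self):
        with pytest.raises(InsufficientDataError):
            interdomain_identity_matrix(_clone_dataset(n=1), 3)

    def test_pair_counts(self):
        n, k = 5, 3
        m = interdomain_identity_matrix(_clone_dataset(n=n, k=k), k)
        assert m.n_pairs[0, 0] == n * (n - 1) // 2
        # off-diagonal: both orientations of each cross pair + one per record
        assert m.n_pairs[0, 1] == n * (n - 1) + n
        m2 = interdomain_identity_matrix(
            _clone_dataset(n=n, k=k), k, include_within_record=False
        )
        assert m2.n_pairs[0, 1] == n * (n - 1)

    def test_subsampling_is_seeded(self):
        ds = Dataset(simulate_dataset(
            SimulationConfig(seed=7, n_records=30,
                             phylum_profile=(("Proteobacteria", 4, 1.0),))
        ).dataset.records)
        m1 = interdomain_identity_matrix(ds, 4, pair_cap=10, subsample_seed=42)
        m2 = interdomain_identity_matrix(ds, 4, pair_cap=10, subsample_seed=42)
        assert np.allclose(m1.values, m2.values)
        assert m1.subsample_seed == 42
        assert m1.n_pairs[0, 0] == 10 * 9 // 2

    def test_output_files(self, tmp_path):
        m = interdomain_identity_matrix(_clone_dataset(), 3)
        m.to_tsv(tmp_path / "m.tsv")
        m.to_json(tmp_path / "m.json")
        assert (tmp_path / "m.tsv").read_text().count("\n") == 3 * 3 + 2


class TestWithinPositionIdentity:
    def test_clones_are_100(self):
        assert within_position_identity(_clone_dataset(), 3, 1) == 100.0

    def test_three_of_four_case(self):
        recs = [
            make_record("A", sequence="ACDE", boundaries=((1, 4),)),
            make_record("B", sequence="ACDF", boundaries=((1, 4),)),
        ]
        assert within_position_identity(Dataset(recs), 1, 1) == 75.0

    def test_bad_index_rejected(self):
        with pytest.raises(ValidationError):
            within_position_identity(_clone_dataset(), 3, 4)

    def test_matches_matrix_diagonal(self, small_family):
        m = interdomain_identity_matrix(small_family.dataset, 6)
        v = within_position_identity(small_family.dataset, 6, 3)
        assert v == pytest.approx(m.cell(3, 3))


class TestReferenceScan:
    def test_one_domain_group_modal_is_1(self):
        recs = [
            make_record(f"R{i}", sequence=sample_ancestral_domain(70, i),
                        boundaries=((1, 70),))
            for i in range(3)
        ]
        res = reference_scan(Dataset(recs), sample_ancestral_domain(70, 99))
        assert len(res) == 1
        assert res[0].group == 1
        assert res[0].modal_index == 1
        assert res[0].n_representatives == 3

    def test_all_domains_equal_reference_tie_to_lowest(self):
        dom = sample_ancestral_domain(40, 0)
        seq = dom * 3
        rec = make_record("A", sequence=seq,
                          boundaries=((1, 40), (41, 80), (81, 120)))
        res = reference_scan(Dataset([rec, make_record("B", sequence=seq,
                             boundaries=((1, 40), (41, 80), (81, 120)))]), dom)
        assert res[0].best_index == {"A": 1, "B": 1}
        assert res[0].modal_index == 1
        assert res[0].mean_identity == 100.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            reference_scan(_clone_dataset(), "")

    def test_planted_domain_found(self):
        fam = simulate_dataset(
            SimulationConfig(seed=17, n_records=30,
                             phylum_profile=(("Proteobacteria", 6, 1.0),))
        )
        res = reference_scan(fam.dataset, fam.truth.ancestral_domain,
                             reference_id="ancestor")
        assert res[0].modal_index == fam.truth.planted_index == 3
        assert res[0].n_representatives > 15


class TestConservedDomainSummary:
    def test_degenerate_clones(self):
        ds = _clone_dataset()
        # make every domain of every record identical: uniform identity
        dom = sample_ancestral_domain(40, 1)
        seq = dom * 3
        bounds = ((1, 40), (41, 80), (81, 120))
        ds = Dataset([make_record(f"C{i}", sequence=seq, boundaries=bounds)
                      for i in range(3)])
        m = interdomain_identity_matrix(ds, 3)
        summary = conserved_domain_summary(m, reference_scan(ds, dom))
        assert summary.degenerate
        assert "degenerate" in summary.note

    def test_planted_conservation_all_locators_agree(self):
        fam = simulate_dataset(
            SimulationConfig(seed=23, n_records=30,
                             phylum_profile=(("Proteobacteria", 6, 1.0),))
        )
        m = interdomain_identity_matrix(fam.dataset, 6)
        scans = reference_scan(fam.dataset, fam.truth.ancestral_domain,
                               reference_id="ancestor")
        summary = conserved_domain_summary(m, scans)
        assert summary.diagonal_argmax == 3
        assert summary.offdiagonal_argmax == (3, 4)
        assert summary.reference_modal == {"ancestor": 3}
        assert summary.agreement

    def test_two_domain_group_restricted(self):
        ds = Dataset(simulate_dataset(
            SimulationConfig(seed=31, n_records=10,
                             phylum_profile=(("Actinobacteria", 2, 1.0),))
        ).dataset.records)
        m = interdomain_identity_matrix(ds, 2)
        summary = conserved_domain_summary(m, [])
        assert summary.diagonal_argmax in (1, 2)
        assert summary.offdiagonal_argmax == (1, 2)

    def test_group_mismatch_rejected(self):
        ds = _clone_dataset()
        m = interdomain_identity_matrix(ds, 3)
        scan = reference_scan(
            Dataset([make_record("Z", sequence="MKVLQ" * 14,
                                 boundaries=((1, 70),))] * 1
                    + [make_record("Y", sequence="MKVLQ" * 14,
                                   boundaries=((1, 70),))]),
            "MKVLQ")
        with pytest.raises(ValidationError):
            conserved_domain_summary(m, scan)
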