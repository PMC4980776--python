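from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sigqsar import (
    SignatureDictionary,
    build_dictionary,
    molecule_signatures,
    parse_smiles,
    read_signature_list,
    read_sparse_matrix,
    vectorize,
    write_signature_list,
    write_sparse_matrix,
)
from sigqsar.featurize import vectorize_multiset, vectors_to_csr, SparseVector

HEIGHTS = (1, 2, 3)


@pytest.fixture(scope="module")
def ethanol_dict():
    eth = parse_smiles("CCO")
    return eth, build_dictionary([molecule_signatures(eth, HEIGHTS)])


class TestDictionary:
    def test_union_is_sorted_with_contiguous_indices(self):
        multisets = [
            molecule_signatures(parse_smiles(s), {1}) for s in ("CCO", "CO")
        ]
        d = build_dictionary(multisets)
        expected = sorted(set(multisets[0]) | set(multisets[1]))
        assert list(d.entries) == expected
        assert [d.index[t] for t in d.entries] == list(range(1, len(d) + 1))

    def test_duplicate_molecule_idempotent(self):
        ms = molecule_signatures(parse_smiles("CCO"), HEIGHTS)
        assert build_dictionary([ms, ms]) == build_dictionary([ms])

    def test_order_stability_under_shuffle(self):
        multisets = [
            molecule_signatures(parse_smiles(s), HEIGHTS)
            for s in ("CCO", "c1ccccc1", "CC(C)C", "CCN")
        ]
        d1 = build_dictionary(multisets)
        d2 = build_dictionary(multisets[::-1])
        assert d1.entries == d2.entries

    def test_round_trip_index_to_text(self, ethanol_dict):
        _, d = ethanol_dict
        for text, i in d.index.items():
            assert d.text_of(i) == text

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            build_dictionary([])

    def test_duplicate_entries_rejected(self):
        with pytest.raises(ValueError):
            SignatureDictionary(("[C]", "[C]"))


class TestVectorize:
    def test_l1_equals_multiset_cardinality(self, ethanol_dict):
        eth, d = ethanol_dict
        vec = vectorize(eth, d, HEIGHTS)
        assert vec.l1() == sum(molecule_signatures(eth, HEIGHTS).values())

    def test_unseen_texts_ignored(self, ethanol_dict):
        _, d = ethanol_dict
        methanol = parse_smiles("CO")
        vec = vectorize(methanol, d, HEIGHTS)
        shared = set(molecule_signatures(methanol, HEIGHTS)) & set(d.entries)
        assert {d.text_of(i) for i in vec.components} == shared

    def test_zero_overlap_gives_empty_vector(self, ethanol_dict):
        _, d = ethanol_dict
        vec = vectorize(parse_smiles("c1ccccc1"), d, HEIGHTS)
        assert vec.components == {}

    def test_binary_mode(self, ethanol_dict):
        eth, d = ethanol_dict
        vec = vectorize(eth, d, HEIGHTS, binary=True)
        assert set(vec.components.values()) == {1.0}

    def test_linearity_over_multiset_union(self, ethanol_dict):
        _, d = ethanol_dict
        a = molecule_signatures(parse_smiles("CCO"), HEIGHTS)
        b = molecule_signatures(parse_smiles("CO"), HEIGHTS)
        combined = vectorize_multiset(a + b, d).components
        va = vectorize_multiset(a, d).components
        vb = vectorize_multiset(b, d).components
        summed = Counter(va)
        summed.update(vb)
        assert combined == dict(summed)

    def test_zero_component_rejected(self):
        with pytest.raises(ValueError):
            SparseVector({1: 0})


class TestLibsvmFormat:
    def test_exact_line_format(self, tmp_path):
        path = tmp_path / "m.libsvm"
        m = vectors_to_csr([SparseVector({1: 2, 5: 1})], 6)
        write_sparse_matrix([2.0], m, path)
        assert path.read_text() == "2.0 1:2 5:1\n"

    def test_empty_record_is_bare_label(self, tmp_path):
        path = tmp_path / "m.libsvm"
        write_sparse_matrix([3.5], vectors_to_csr([SparseVector({})], 4), path)
        assert path.read_text() == "3.5\n"

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_round_trip_random_records(self, seed):
        import os
        import tempfile

        rng = np.random.default_rng(seed)
        n, p = int(rng.integers(1, 20)), int(rng.integers(1, 15))
        vecs = []
        for _ in range(n):
            cols = rng.choice(p, size=rng.integers(0, p + 1), replace=False)
            vecs.append(SparseVector({int(c) + 1: float(rng.integers(1, 9)) for c in cols}))
        labels = rng.normal(size=n)
        matrix = vectors_to_csr(vecs, p)
        fd, path = tempfile.mkstemp(suffix=".libsvm")
        os.close(fd)
        try:
            write_sparse_matrix(labels, matrix, path)
            labels2, matrix2 = read_sparse_matrix(path, n_features=p)
        finally:
            os.unlink(path)
        assert np.allclose(labels, labels2)
        assert (matrix != matrix2).nnz == 0

    def test_sklearn_reads_our_format(self, tmp_path):
        """Cross-check the writer against an independent LIBSVM reader."""
        from sklearn.datasets import load_svmlight_file

        path = tmp_path / "m.libsvm"
        vecs = [SparseVector({1: 2, 3: 1}), SparseVector({2: 4.5})]
        write_sparse_matrix([1.0, -2.0], vectors_to_csr(vecs, 3), path)
        X, y = load_svmlight_file(str(path), n_features=3)
        assert np.allclose(y, [1.0, -2.0])
        assert np.allclose(X.toarray(), [[2, 0, 1], [0, 4.5, 0]])

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.libsvm"
        path.write_text("1.0 1:2\n2.0 oops\n")
        with pytest.raises(ValueError, match="line 2"):
            read_sparse_matrix(path)

    def test_non_ascending_indices_rejected(self, tmp_path):
        path = tmp_path / "bad.libsvm"
        path.write_text("1.0 3:1 2:1\n")
        with pytest.raises(ValueError, match="line 1"):
            read_sparse_matrix(path)


class TestSignatureList:
    def test_line_count_and_round_trip(self, tmp_path, ethanol_dict):
        _, d = ethanol_dict
        path = tmp_path / "signatures.txt"
        size = write_signature_list(d, path)
        assert size == len(path.read_bytes())
        assert len(path.read_text().splitlines()) == len(d)
        assert read_signature_list(path) == d

    def test_single_entry_difference_is_one_line(self, tmp_path):
        d1 = SignatureDictionary(("[C]", "[N]", "[O]"))
        d2 = SignatureDictionary(("[C]", "[N]", "[S]"))
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_signature_list(d1, p1)
        write_signature_list(d2, p2)
        diff = [
            (a, b)
            for a, b in zip(p1.read_text().splitlines(), p2.read_text().splitlines())
            if a != b
        ]
        assert len(diff) == 1

    def test_duplicate_line_rejected(self, tmp_path):
        path = tmp_path / "signatures.txt"
        path.write_text("[C]\n[O]\n[C]\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_signature_list(path)
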