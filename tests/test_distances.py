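import numpy as np
import pytest

from cypevol.alignment import codon_alignment_from_dict, \
    protein_alignment_from_dict
from cypevol.distances import (DistanceMatrix, SiteFilterPolicy,
                               distance_matrix, filter_columns,
                               identity_fraction, jtt_distance, p_distance)


def test_filter_columns_strictly_greater():
    # column gap fractions: 0, 1/3, 2/3 with threshold 1/3 -> drop only 2/3
    aln = protein_alignment_from_dict({"a": "MK-", "b": "M--", "c": "MKL"})
    out = filter_columns(aln, SiteFilterPolicy(max_gap_fraction=1 / 3))
    assert out.n_columns == 2
    assert out.column_positions.tolist() == [1, 2]


def test_p_distance_pairwise_vs_complete():
    aln = protein_alignment_from_dict({"a": "MKLR", "b": "MSL-", "c": "MKLR"})
    pol_pair = SiteFilterPolicy(max_gap_fraction=1.0, deletion_mode="pairwise")
    pol_comp = SiteFilterPolicy(max_gap_fraction=1.0, deletion_mode="complete")
    # pairwise a-b: 3 comparable, 1 diff
    assert p_distance(aln, 0, 1, pol_pair) == pytest.approx(1 / 3)
    # complete deletion drops column 4 for everyone
    assert p_distance(aln, 0, 2, pol_comp) == pytest.approx(0.0)
    assert p_distance(aln, 0, 1, pol_comp) == pytest.approx(1 / 3)


def test_identity_fraction():
    aln = protein_alignment_from_dict({"a": "MKLR", "b": "MKLV"})
    assert identity_fraction(aln, 0, 1) == pytest.approx(0.75)


def test_jtt_distance_properties():
    near = protein_alignment_from_dict({"a": "MKLRVVAEW" * 20,
                                        "b": "MKLRVVAEW" * 20})
    assert jtt_distance(near, 0, 1) == pytest.approx(0.0, abs=1e-6)
    rng = np.random.default_rng(0)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    s1 = "".join(rng.choice(aas, size=300))
    s2 = list(s1)
    # introduce ~10% random replacements
    for i in rng.choice(300, size=30, replace=False):
        s2[i] = rng.choice([a for a in aas if a != s2[i]])
    far = protein_alignment_from_dict({"a": s1, "b": "".join(s2)})
    d = jtt_distance(far, 0, 1)
    pd = p_distance(far, 0, 1)
    assert d > pd  # ML distance corrects upward
    assert 0.05 < d < 0.3


def test_distance_matrix_symmetry_and_tsv(tmp_path):
    aln = codon_alignment_from_dict({
        "a": "ATGAAATTTCCC", "b": "ATGAAGTTTCCC", "c": "ATGAAATTCCCC"})
    D = distance_matrix(aln, method="p")
    assert D.values.shape == (3, 3)
    assert np.allclose(D.values, D.values.T)
    assert np.allclose(np.diag(D.values), 0.0)
    p = tmp_path / "d.tsv"
    D.to_tsv(p)
    back = DistanceMatrix.from_tsv(p)
    assert back.labels == D.labels
    assert np.allclose(back.values, D.values)
    assert back.method == "p"


def test_ds_dn_matrix_on_synonymous_difference():
    # AAA->AAG is synonymous (Lys); dN must be 0, dS positive
    aln = codon_alignment_from_dict({"a": "AAATTT", "b": "AAGTTT"})
    ds = distance_matrix(aln, method="dS", correction="none")
    dn = distance_matrix(aln, method="dN", correction="none")
    assert ds[("a", "b")] > 0
    assert dn[("a", "b")] == 0


def test_invalid_method():
    aln = codon_alignment_from_dict({"a": "AAATTT", "b": "AAGTTT"})
    with pytest.raises(ValueError):
        distance_matrix(aln, method="nope")
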