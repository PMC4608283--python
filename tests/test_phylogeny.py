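"""RT extraction, distance matrices, neighbor joining, lineage assignment."""

import math
from io import StringIO

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

from palm_ltr.detector import LTRElement
from palm_ltr.domains import classify_superfamily, scan_domains
from palm_ltr.phylogeny import (DistanceMatrix, assign_lineages, extract_rt,
                                neighbor_joining, pairwise_distance_matrix)
from palm_ltr.synthetic import ElementSpec, build_element

AA = "ACDEFGHIKLMNPQRSTVWY"


def _mutated(seq, rate, rng):
    return "".join(c if rng.random() > rate
                   else rng.choice([a for a in AA if a != c]) for c in seq)


def _random_additive_tree(n, rng):
    """Random bifurcating tree with positive branch lengths -> (newick, ids)."""
    ids = [f"T{i}" for i in range(n)]
    nodes = list(ids)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        la, lb = rng.uniform(0.5, 5.0, size=2)
        merged = f"({a}:{la:.6f},{b}:{lb:.6f})"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    return nodes[0] + ";", ids


def _path_distances(newick, ids):
    tree = TreeNode.read(StringIO(newick), convert_underscores=False)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tree.find(ids[i]).distance(tree.find(ids[j]))
            mat[i, j] = mat[j, i] = d
    return mat


class TestExtractRT:
    def _classified(self, spec, seed, domain_library):
        truth = build_element(spec, seed)
        elem = LTRElement("e", "s", 0, len(truth.sequence), truth.ltr5,
                          truth.ltr3, 0.95)
        hits = scan_domains(truth.sequence, domain_library)
        return classify_superfamily(hits, elem), truth

    def test_planted_rt_recovered_near_reference(self, domain_library):
        ce, truth = self._classified(ElementSpec(superfamily="Copia",
                                                 lineage="Tork"), 4,
                                     domain_library)
        rt = extract_rt(ce, truth.sequence)
        ref = next(r.sequence for r in domain_library
                   if r.kind == "RT" and r.lineage == "Tork")
        assert rt is not None
        assert ref in rt or rt in ref or \
            sum(a == b for a, b in zip(rt, ref)) >= 0.95 * min(len(rt),
                                                               len(ref))

    def test_short_rt_hit_yields_absent(self, domain_library):
        ce, truth = self._classified(ElementSpec(superfamily="Copia"), 5,
                                     domain_library)
        assert extract_rt(ce, truth.sequence, min_residues=10_000) is None

    def test_non_autonomous_element_yields_absent(self, domain_library):
        ce, truth = self._classified(
            ElementSpec(superfamily="NA", domain_list=("GAG",),
                        internal_length=1500), 6, domain_library)
        assert extract_rt(ce, truth.sequence) is None


class TestDistances:
    def test_identical_sequences_distance_zero(self):
        seqs = {"a": "MKVLAWTRRQST" * 10, "b": "MKVLAWTRRQST" * 10}
        dm = pairwise_distance_matrix(seqs)
        assert dm.get("a", "b") == 0.0

    def test_poisson_correction_closed_form(self, rng):
        base = "".join(rng.choice(list(AA), size=200))
        # exactly 10 % substitutions, no gaps expected at this similarity
        idx = rng.choice(200, size=20, replace=False)
        other = list(base)
        for i in idx:
            other[i] = next(a for a in AA if a != base[i])
        dm = pairwise_distance_matrix({"a": base, "b": "".join(other)})
        assert dm.get("a", "b") == pytest.approx(-math.log(0.9), abs=1e-6)

    def test_symmetry_and_validation(self, rng):
        seqs = {f"s{i}": "".join(rng.choice(list(AA), size=80))
                for i in range(4)}
        dm = pairwise_distance_matrix(seqs)
        assert np.allclose(dm.matrix, dm.matrix.T)
        with pytest.raises(ValueError):
            pairwise_distance_matrix({"a": "MKV"})
        with pytest.raises(ValueError):
            pairwise_distance_matrix({"a": "MKV", "b": ""})


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_reproduced_exactly(self):
        ids = ["A", "B", "C", "D"]
        mat = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                        [5, 6, 0, 7], [6, 7, 7, 0]], float)
        newick = neighbor_joining(DistanceMatrix(ids, mat))
        paths = _path_distances(newick, ids)
        assert np.allclose(paths, mat, atol=1e-9)

    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        mat = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        newick = neighbor_joining(DistanceMatrix(ids, mat))
        paths = _path_distances(newick, ids)
        assert np.allclose(paths, mat, atol=1e-9)

    def test_random_additive_matrices_reproduced(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            newick_true, ids = _random_additive_tree(n, rng)
            mat = _path_distances(newick_true, ids)
            newick = neighbor_joining(DistanceMatrix(ids, mat))
            assert np.allclose(_path_distances(newick, ids), mat, atol=1e-9)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(8)
        newick_true, ids = _random_additive_tree(6, rng)
        mat = _path_distances(newick_true, ids)
        a = neighbor_joining(DistanceMatrix(ids, mat))
        perm = [3, 0, 5, 1, 4, 2]
        b = neighbor_joining(DistanceMatrix(
            [ids[i] for i in perm], mat[np.ix_(perm, perm)]))
        assert a == b

    def test_agrees_with_independent_nj_on_noisy_matrix(self):
        """Same topology as scikit-bio's neighbor joining on a non-additive
        matrix (robinson-foulds distance zero)."""
        rng = np.random.default_rng(9)
        newick_true, ids = _random_additive_tree(7, rng)
        mat = _path_distances(newick_true, ids)
        mat += rng.uniform(0, 0.05, mat.shape)
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        mine = TreeNode.read(StringIO(neighbor_joining(
            DistanceMatrix(ids, mat))), convert_underscores=False)
        theirs = skbio_nj(SkbioDM(mat, ids))
        assert mine.compare_rfd(theirs) == 0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"],
                                            np.array([[0, 1], [1, 0.]])))


class TestLineageAssignment:
    def test_mutated_references_recover_their_lineages(self, domain_library):
        rng = np.random.default_rng(3)
        elements = {}
        expected = {}
        for lineage in ("Tork", "Oryco", "Athila", "Reina"):
            ref = next(r for r in domain_library if r.lineage == lineage)
            elements[f"el_{lineage}"] = _mutated(ref.sequence, 0.05, rng)
            expected[f"el_{lineage}"] = lineage
        for a in assign_lineages(elements, domain_library):
            assert a.lineage == expected[a.element_id]
            assert a.support < 0.15

    def test_equidistant_chimera_is_undefined(self, domain_library):
        # take exactly half of the differing sites from each parent so the
        # chimera is equidistant between the two lineages' references
        tork = next(r for r in domain_library if r.lineage == "Tork").sequence
        sire = next(r for r in domain_library if r.lineage == "Sire").sequence
        diff = [i for i, (a, b) in enumerate(zip(tork, sire)) if a != b]
        chimera = list(tork)
        for rank, i in enumerate(diff):
            if rank % 2:
                chimera[i] = sire[i]
        res = assign_lineages({"chimera": "".join(chimera)}, domain_library)
        assert res[0].lineage == "undefined"

    def test_no_elements_returns_empty(self, domain_library):
        assert assign_lineages({}, domain_library) == []

    def test_no_references_rejected(self):
        with pytest.raises(ValueError):
            assign_lineages({"e": "MKVL" * 50}, [])
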