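"""Modified-cosine scoring and network construction."""

import itertools

import numpy as np
import pytest

from mycoderep.molecular_network import (
    build_network,
    cluster_spectra,
    cosine_score,
    split_nodes_by_rt,
)
from mycoderep.spectra_features import FragmentSpectrum


def _spec(sid, precursor, peaks, polarity="positive", rt=1.0, group="G1"):
    return FragmentSpectrum(sid, precursor, polarity, rt, tuple(peaks), group)


def brute_force_cosine(a, b, frag_tol, allow_precursor_shift=True):
    """Exhaustive maximum over all one-to-one fragment pairings (oracle)."""
    sa, sb = np.sqrt(a.intensity_array), np.sqrt(b.intensity_array)
    shift = a.precursor_mz - b.precursor_mz
    eligible = {
        (i, j)
        for i in range(len(sa))
        for j in range(len(sb))
        if abs(a.mz_array[i] - b.mz_array[j]) <= frag_tol
        or (allow_precursor_shift and abs(a.mz_array[i] - b.mz_array[j] - shift) <= frag_tol)
    }
    norm = float(np.linalg.norm(sa) * np.linalg.norm(sb))
    best = 0.0
    k_max = min(len(sa), len(sb))
    for k in range(1, k_max + 1):
        for rows in itertools.combinations(range(len(sa)), k):
            for cols in itertools.permutations(range(len(sb)), k):
                if all((i, j) in eligible for i, j in zip(rows, cols)):
                    best = max(best, sum(sa[i] * sb[j] for i, j in zip(rows, cols)))
    return best / norm


class TestCosineScore:
    def test_self_similarity(self):
        s = _spec("a", 400.0, [(100.0, 5.0), (150.0, 2.0), (210.4, 9.0)])
        cosine, n = cosine_score(s, s)
        assert cosine == pytest.approx(1.0)
        assert n == 3

    def test_disjoint_support(self):
        a = _spec("a", 400.0, [(100.0, 1.0), (110.0, 1.0)])
        b = _spec("b", 400.0, [(150.0, 1.0), (160.0, 1.0)])
        assert cosine_score(a, b, frag_tol=0.3) == (0.0, 0)

    def test_polarity_mismatch_raises(self):
        a = _spec("a", 400.0, [(100.0, 1.0)])
        b = _spec("b", 400.0, [(100.0, 1.0)], polarity="negative")
        with pytest.raises(ValueError, match="polarity"):
            cosine_score(a, b)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = _spec("a", 400 + rng.uniform(0, 3), [(float(m), float(i)) for m, i in
                      zip(rng.uniform(100, 160, 5), rng.uniform(1, 10, 5))])
            b = _spec("b", 400 + rng.uniform(0, 3), [(float(m), float(i)) for m, i in
                      zip(rng.uniform(100, 160, 5), rng.uniform(1, 10, 5))])
            cab, _ = cosine_score(a, b, frag_tol=2.0)
            cba, _ = cosine_score(b, a, frag_tol=2.0)
            assert cab == pytest.approx(cba, abs=1e-9)
            assert 0.0 <= cab <= 1.0

    def test_modified_at_least_plain(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = _spec("a", 420 + rng.uniform(0, 8), [(float(m), float(i)) for m, i in
                      zip(rng.uniform(100, 200, 6), rng.uniform(1, 10, 6))])
            b = _spec("b", 400.0, [(float(m), float(i)) for m, i in
                      zip(rng.uniform(100, 200, 6), rng.uniform(1, 10, 6))])
            plain, _ = cosine_score(a, b, frag_tol=1.0, allow_precursor_shift=False)
            modified, _ = cosine_score(a, b, frag_tol=1.0, allow_precursor_shift=True)
            assert modified >= plain - 1e-12

    @pytest.mark.parametrize("allow_shift", [False, True])
    def test_equals_brute_force_on_small_spectra(self, allow_shift):
        """Exact-matching cosine equals exhaustive enumeration, <= 6 peaks."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            na, nb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            a = _spec("a", 400 + float(rng.uniform(0, 5)), [(float(m), float(i)) for m, i in
                      zip(rng.uniform(100, 140, na), rng.uniform(1, 10, na))])
            b = _spec("b", 400 + float(rng.uniform(0, 5)), [(float(m), float(i)) for m, i in
                      zip(rng.uniform(100, 140, nb), rng.uniform(1, 10, nb))])
            got, _ = cosine_score(a, b, frag_tol=4.0, allow_precursor_shift=allow_shift)
            oracle = brute_force_cosine(a, b, 4.0, allow_shift)
            assert got == pytest.approx(oracle, abs=1e-9)

    def test_ambiguous_pairing_resolved_optimally(self):
        # two a-peaks both eligible for one b-peak: the optimal assignment
        # must take the high-intensity product, not the greedy first match
        a = _spec("a", 400.0, [(100.0, 1.0), (100.2, 100.0), (130.0, 4.0), (140.0, 4.0)])
        b = _spec("b", 400.0, [(100.1, 100.0), (130.1, 4.0), (140.1, 4.0), (170.0, 1.0)])
        got, _ = cosine_score(a, b, frag_tol=0.3, allow_precursor_shift=False)
        assert got == pytest.approx(brute_force_cosine(a, b, 0.3, False), abs=1e-9)


class TestBuildNetwork:
    def _chain(self):
        # A-B and B-C share >= 4 fragments; A-C share fewer
        base = [(100.0, 5.0), (110.0, 5.0), (120.0, 5.0), (130.0, 5.0)]
        a = _spec("A", 400.0, base + [(140.0, 5.0)])
        b = _spec("B", 410.0, base + [(150.0, 5.0)])
        c = _spec("C", 420.0, base + [(160.0, 5.0)])
        return [a, b, c]

    def test_chain_forms_single_component(self):
        net = build_network(self._chain(), cosine_min=0.7, min_matched=4)
        assert len(net.nodes) == 3
        assert len(net.edges) >= 2

    def test_isolated_node_removed(self):
        spectra = self._chain() + [_spec("D", 900.0, [(500.0, 1.0), (600.0, 1.0)])]
        net = build_network(spectra)
        assert all("D" not in n.members[0].spectrum_id for n in net.nodes)

    def test_min_cluster_invariant(self):
        net = build_network(self._chain() + [_spec("D", 900.0, [(500.0, 1.0)])])
        graph = net.graph()
        import networkx as nx

        for comp in nx.connected_components(graph):
            assert len(comp) >= 2

    def test_below_threshold_pair_removed(self):
        a = _spec("A", 400.0, [(100.0, 5.0), (110.0, 5.0), (200.0, 9.0), (210.0, 9.0)])
        b = _spec("B", 400.0, [(100.0, 5.0), (110.0, 5.0), (300.0, 9.0), (310.0, 9.0)])
        cosine, _ = cosine_score(a, b)
        assert cosine < 0.7  # sanity: this pair sits below the edge threshold
        net = build_network([a, b])
        assert len(net.nodes) == 0

    def test_raising_cosine_never_adds_edges(self):
        spectra = self._chain()
        loose = build_network(spectra, cosine_min=0.5)
        strict = build_network(spectra, cosine_min=0.9)
        loose_edges = {(e.node_a, e.node_b) for e in loose.edges}
        strict_edges = {(e.node_a, e.node_b) for e in strict.edges}
        assert strict_edges <= loose_edges

    def test_empty_input(self):
        net = build_network([])
        assert net.nodes == () and net.edges == ()


class TestSplitNodesByRt:
    def _isomer_network(self):
        peaks = [(100.0, 5.0), (110.0, 5.0), (120.0, 5.0), (130.0, 5.0)]
        early = _spec("iso-early", 364.4, peaks, rt=4.0, group="G2")
        late = _spec("iso-late", 364.4, peaks, rt=12.0, group="G5")
        other = _spec("other", 364.4, peaks, rt=4.1, group="G3")
        return build_network([early, late, other], min_cluster=1)

    def test_coeluting_node_unchanged(self):
        peaks = [(100.0, 5.0), (110.0, 5.0)]
        net = build_network(
            [_spec("a", 400.0, peaks, rt=5.0), _spec("b", 400.0, peaks, rt=5.1)],
            min_cluster=1,
        )
        split = split_nodes_by_rt(net, rt_tol=0.5)
        assert len(split.nodes) == len(net.nodes)

    def test_distant_isomers_split(self):
        net = self._isomer_network()
        assert len(net.nodes) == 1  # clustering pooled the isomers
        split = split_nodes_by_rt(net, rt_tol=0.5)
        assert len(split.nodes) == 2

    def test_intensity_conserved(self):
        net = self._isomer_network()
        split = split_nodes_by_rt(net, rt_tol=0.5)
        assert split.total_intensity == pytest.approx(net.total_intensity)

    def test_group_shares_no_longer_pooled(self, noise_free_experiment):
        spectra = [
            s
            for g, specs in noise_free_experiment.spectra.items()
            for s in specs
            if s.polarity == "positive"
        ]
        net = build_network(spectra, min_cluster=1)
        split = split_nodes_by_rt(net, rt_tol=0.5)
        iso_nodes = [
            n
            for n in split.nodes
            if any(m.spectrum_id.startswith("M7") for m in n.members)
        ]
        assert len(iso_nodes) == 2
        for node in iso_nodes:
            met_ids = {m.spectrum_id.split(":")[0] for m in node.members}
            assert len(met_ids) == 1  # each sub-node holds exactly one isomer

    def test_node_shares_sum_to_total(self, noise_free_experiment):
        spectra = [
            s
            for specs in noise_free_experiment.spectra.values()
            for s in specs
            if s.polarity == "negative"
        ]
        net = build_network(spectra, min_cluster=1)
        for node in net.nodes:
            assert sum(node.group_shares.values()) == pytest.approx(node.total_intensity)
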