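"""Feature engineering: logos, segments, averages, overlaps, palindromes,
centralities, and the assembled table."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delpath.features import (
    FeatureExtractor,
    build_position_logo,
    content_average,
    context_bitscores,
    extract_segments,
    find_palindromes,
    network_centralities,
    overlap_flags,
    position_features,
)
from delpath.io import (
    AnnotationTrack,
    DeletionVariant,
    PropertyScale,
    ProteinRecord,
)

LOG2_20 = math.log2(20)


def _protein(seq, pid="P1"):
    return ProteinRecord(pid, seq)


class TestPositionLogo:
    def test_single_letter_column_has_full_information(self):
        # every training window shows 'A' immediately downstream
        proteins = {f"P{i}": _protein("MKLVA" + "Q" * 10, f"P{i}") for i in range(3)}
        variants = [DeletionVariant(f"P{i}", 3, 4, label="benign") for i in range(3)]
        logo = build_position_logo(variants, proteins, "benign")
        assert logo.info[1] == pytest.approx(LOG2_20)
        assert logo.bit_score("A", 1) == pytest.approx(LOG2_20)

    def test_two_residue_column_entropy(self):
        # offset -1 observes {A, C}: info = log2 20 - 1, bit scores split evenly
        proteins = {
            "PA": _protein("MAXDEL" + "Q" * 5, "PA"),
            "PC": _protein("MCXDEL" + "Q" * 5, "PC"),
        }
        variants = [
            DeletionVariant("PA", 3, 3, label="benign"),
            DeletionVariant("PC", 3, 3, label="benign"),
        ]
        logo = build_position_logo(variants, proteins, "benign")
        assert logo.info[-1] == pytest.approx(LOG2_20 - 1.0)
        assert logo.bit_score("A", -1) == pytest.approx((LOG2_20 - 1.0) / 2)
        assert logo.bit_score("C", -1) == pytest.approx((LOG2_20 - 1.0) / 2)

    def test_uniform_usage_gives_zero_information(self):
        # 20 training variants, each with a different residue at offset +1
        proteins = {}
        variants = []
        for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY"):
            pid = f"P{i}"
            proteins[pid] = _protein("MKL" + aa + "QQQQ", pid)
            variants.append(DeletionVariant(pid, 2, 3, label="benign"))
        logo = build_position_logo(variants, proteins, "benign")
        assert logo.info[1] == pytest.approx(0.0, abs=1e-12)
        assert logo.bit_score("A", 1) == pytest.approx(0.0, abs=1e-12)

    def test_unobserved_offset_is_uniform_zero_info(self):
        # deletion at position 2 of a short protein: offset -2 never exists
        proteins = {"P1": _protein("MAQWERT")}
        variants = [DeletionVariant("P1", 2, 2, label="benign")]
        logo = build_position_logo(variants, proteins, "benign")
        assert logo.info[-2] == 0.0
        assert sum(logo.freqs[-2].values()) == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=20)
    def test_frequencies_sum_to_one_and_info_in_range(self, seed):
        rng = np.random.default_rng(seed)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        proteins, variants = {}, []
        for i in range(rng.integers(1, 8)):
            pid = f"P{i}"
            length = int(rng.integers(5, 30))
            proteins[pid] = _protein("".join(rng.choice(letters, length)), pid)
            start = int(rng.integers(2, length + 1))
            end = min(length, start + int(rng.integers(0, 3)))
            variants.append(DeletionVariant(pid, start, end, label="benign"))
        logo = build_position_logo(variants, proteins, "benign")
        for offset, freqs in logo.freqs.items():
            assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-9)
            assert 0.0 <= logo.info[offset] <= LOG2_20 + 1e-12


class TestContextBitscores:
    def _logo_all_A_down1(self):
        proteins = {f"P{i}": _protein("MKLVA" + "Q" * 10, f"P{i}") for i in range(2)}
        variants = [DeletionVariant(f"P{i}", 3, 4, label="benign") for i in range(2)]
        return build_position_logo(variants, proteins, "benign")

    def test_downstream_lookup(self):
        logo = self._logo_all_A_down1()
        protein = _protein("MKLVAQQQQQ")
        v = DeletionVariant("P1", 3, 4)
        scores = context_bitscores(v, protein, {"benign": logo})
        # residue 'A' at offset +1 carries the full 4.32 bits; the other
        # downstream offsets observe 'Q' only, adding log2(20) each as well
        assert scores["ctx_down_benign"] >= LOG2_20
        assert scores["ctx_up_benign"] >= 0.0

    def test_terminus_clipping_uses_only_existing_offsets(self):
        logo = self._logo_all_A_down1()
        protein = _protein("MAQWERTYKL")
        v = DeletionVariant("P1", 2, 2)  # a single upstream residue exists
        scores = context_bitscores(v, protein, {"benign": logo})
        max_single = max(logo.info.get(-1, 0.0), 0.0)
        assert 0.0 <= scores["ctx_up_benign"] <= max_single + 1e-9

    def test_unseen_residue_contributes_zero(self):
        logo = self._logo_all_A_down1()
        protein = _protein("MKWWWWWWWW")  # downstream residues never observed
        v = DeletionVariant("P1", 2, 2)
        scores = context_bitscores(v, protein, {"benign": logo})
        assert scores["ctx_down_benign"] == pytest.approx(0.0)

    def test_sums_are_non_negative(self, small_proteome):
        proteome, variants, _ = small_proteome
        benign = [v for v in variants if v.label == "benign"]
        path = [v for v in variants if v.label == "pathogenic"]
        logos = {
            "benign": build_position_logo(benign, proteome.proteins, "benign"),
            "pathogenic": build_position_logo(path, proteome.proteins, "pathogenic"),
        }
        for v in variants[:30]:
            scores = context_bitscores(v, proteome.proteins[v.protein_id], logos)
            for key in ("ctx_up_benign", "ctx_up_pathogenic", "ctx_down_benign", "ctx_down_pathogenic"):
                assert scores[key] >= 0.0


class TestSegments:
    def test_stated_convention(self, toy_protein):
        seg = extract_segments(DeletionVariant("P1", 5, 6), toy_protein)
        assert seg.upstream_seg == "XMKLV"
        assert seg.deletion_seg == "NAXXX"
        assert seg.downstream_seg == "QWERT"

    def test_near_n_terminus_padding(self, toy_protein):
        seg = extract_segments(DeletionVariant("P1", 2, 2), toy_protein)
        assert seg.upstream_seg == "XXXXM"

    def test_long_deletion_trimmed_to_first_five(self):
        protein = _protein("M" + "ACDEFGHIKL" + "QWERTY")
        seg = extract_segments(DeletionVariant("P1", 2, 11), protein)
        assert seg.deletion_seg == "ACDEF"


class TestContentAverage:
    SCALE = PropertyScale(
        "TOY",
        {**{aa: 0.0 for aa in "CDEFHIKLMNPQRSTVWY"}, "A": 1.0, "G": 3.0},
    )

    def test_mean_over_deleted(self):
        protein = _protein("MKAGQWERTY")
        assert content_average(DeletionVariant("P1", 3, 4), protein, self.SCALE) == 2.0

    def test_single_residue(self):
        protein = _protein("MKAGQWERTY")
        assert content_average(DeletionVariant("P1", 3, 3), protein, self.SCALE) == 1.0

    def test_x_excluded_from_denominator(self):
        protein = _protein("MKAXGWERTY")
        assert content_average(DeletionVariant("P1", 3, 5), protein, self.SCALE) == 2.0

    def test_all_nonstandard_unavailable(self):
        protein = _protein("MKXXGWERTY")
        assert content_average(DeletionVariant("P1", 3, 4), protein, self.SCALE) is None


class TestPositionFeatures:
    def test_stated_examples(self):
        protein = _protein("A" * 100)
        f = position_features(DeletionVariant("P1", 5, 6), protein)
        assert f["pos_length"] == 2
        assert f["pos_relative"] == pytest.approx(0.055)
        assert f["pos_term_distance"] == 4

        f = position_features(DeletionVariant("P1", 100, 100), protein)
        assert f["pos_term_distance"] == 0

        f = position_features(DeletionVariant("P1", 48, 53), protein)
        assert f["pos_relative"] == pytest.approx(0.505)


class TestOverlapFlags:
    def test_overlap_and_adjacency(self):
        track = AnnotationTrack("P1", "domain", [(6, 40)])
        v = DeletionVariant("P1", 5, 6)
        assert overlap_flags(v, [track])["domain"] == 1
        track2 = AnnotationTrack("P1", "domain", [(7, 40)])
        assert overlap_flags(v, [track2])["domain"] == 0

    def test_absent_category_is_zero(self):
        v = DeletionVariant("P1", 5, 6)
        flags = overlap_flags(v, [], categories=["domain", "IDR"])
        assert flags == {"domain": 0, "IDR": 0}

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=30)
    def test_matches_brute_force_intersection(self, seed):
        rng = np.random.default_rng(seed)
        categories = ["a", "b", "c"]
        tracks = []
        intervals = {c: [] for c in categories}
        for c in categories:
            for _ in range(rng.integers(0, 4)):
                s = int(rng.integers(1, 50))
                e = s + int(rng.integers(0, 10))
                intervals[c].append((s, e))
            if intervals[c]:
                tracks.append(AnnotationTrack("P1", c, sorted(intervals[c])))
        start = int(rng.integers(2, 45))
        end = start + int(rng.integers(0, 6))
        v = DeletionVariant("P1", start, end)
        flags = overlap_flags(v, tracks, categories)
        for c in categories:
            expected = int(
                any(
                    len(set(range(s, e + 1)) & set(range(start, end + 1))) > 0
                    for s, e in intervals[c]
                )
            )
            assert flags[c] == expected


def brute_force_palindromes(seq, min_len):
    """O(n^3) oracle: every substring checked against its reverse."""
    hits = set()
    n = len(seq)
    for i in range(n):
        for j in range(i + min_len - 1, n):
            sub = seq[i : j + 1]
            if sub == sub[::-1]:
                hits.add((i + 1, j + 1))
    return {
        (s, e)
        for s, e in hits
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in hits)
    }


class TestPalindromes:
    def test_whole_string_palindrome_is_maximal(self):
        assert find_palindromes("MKAQAKM", 5) == {(1, 7)}

    def test_no_palindrome(self):
        assert find_palindromes("ACDEF", 3) == set()

    def test_homopolymer(self):
        assert find_palindromes("AAAAA", 3) == {(1, 5)}

    @given(st.text(alphabet="ACDG", min_size=0, max_size=50), st.integers(2, 6))
    @settings(derandomize=True, max_examples=100)
    def test_matches_cubic_oracle(self, seq, min_len):
        assert find_palindromes(seq, min_len) == brute_force_palindromes(seq, min_len)


def brute_force_centralities(edges):
    """Shortest-path / dense-eigen oracle for small graphs."""
    nodes = sorted({u for u, v, w in edges} | {v for u, v, w in edges})
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for u, v, w in edges:
        adj[index[u], index[v]] = adj[index[v], index[u]] = w
    # unweighted hop distances by BFS
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        seen = {s}
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u, v] > 0 and v not in seen:
                        seen.add(v)
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    out = {}
    # betweenness by path enumeration over all simple paths
    bet = {node: 0.0 for node in nodes}
    for si, ti in itertools.combinations(range(n), 2):
        if not np.isfinite(dist[si, ti]):
            continue
        shortest = []
        target = dist[si, ti]
        # enumerate all paths of the shortest length by DFS
        stack = [(si, [si])]
        while stack:
            u, path = stack.pop()
            if u == ti and len(path) - 1 == target:
                shortest.append(path)
                continue
            if len(path) - 1 >= target:
                continue
            for v in range(n):
                if adj[u, v] > 0 and v not in path:
                    stack.append((v, path + [v]))
        for path in shortest:
            for mid in path[1:-1]:
                bet[nodes[mid]] += 1.0 / len(shortest)
    eigvals, eigvecs = np.linalg.eigh(adj)
    hub = np.abs(eigvecs[:, np.argmax(eigvals)])
    hub = hub / hub.max() if hub.max() > 0 else hub
    lam = eigvals.max()
    beta = 0.9 / lam
    power = np.linalg.solve(np.eye(n) - beta * adj, adj @ np.ones(n))
    power *= math.sqrt(n) / np.linalg.norm(power)
    for i, node in enumerate(nodes):
        reach = np.isfinite(dist[i]) & (np.arange(n) != i)
        total = dist[i][reach].sum()
        closeness = (reach.sum() / total) * (reach.sum() / (n - 1)) if total > 0 else 0.0
        out[node] = {
            "degree": float((adj[i] > 0).sum()),
            "closeness": closeness,
            "betweenness": bet[node],
            "harmonic": float((1.0 / dist[i][reach]).sum()) if reach.any() else 0.0,
            "hub_score": float(hub[i]),
            "power": float(power[i]),
        }
    return out


class TestCentralities:
    def test_path_graph(self):
        cents = network_centralities([("A", "B", 1.0), ("B", "C", 1.0)])
        assert cents["B"]["degree"] == 2
        assert cents["B"]["betweenness"] == pytest.approx(1.0)
        assert cents["B"]["closeness"] == pytest.approx(1.0)

    def test_triangle_betweenness_zero(self):
        cents = network_centralities(
            [("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0)]
        )
        assert all(c["betweenness"] == pytest.approx(0.0) for c in cents.values())

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=15, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nodes = ["A", "B", "C", "D", "E"]
        edges = []
        for i in range(5):
            for j in range(i + 1, 5):
                if rng.random() < 0.5:
                    edges.append((nodes[i], nodes[j], 1.0))
        if not edges:
            edges = [("A", "B", 1.0)]
        got = network_centralities(edges)
        expected = brute_force_centralities(edges)
        for node in expected:
            for metric in ("degree", "closeness", "betweenness", "harmonic", "hub_score", "power"):
                assert got[node][metric] == pytest.approx(
                    expected[node][metric], abs=1e-8
                ), f"{node}/{metric}"


class TestFeatureExtractor:
    def test_deterministic_and_order_invariant(self, small_proteome, scales):
        from delpath.simulate import providers_for

        proteome, variants, _ = small_proteome
        ex = FeatureExtractor(
            proteome.proteins, scales=scales, tracks=proteome.tracks,
            providers=providers_for(proteome),
        ).fit(variants)
        t1 = ex.transform(variants)
        t2 = ex.transform(variants)
        assert t1.data.equals(t2.data)
        t3 = ex.transform(list(reversed(variants)))
        assert t1.data.sort_index().equals(t3.data.sort_index())

    def test_missing_provider_excludes_variant(self, small_proteome, scales):
        from delpath.features import ResidueTrackProvider
        from delpath.simulate import providers_for

        proteome, variants, _ = small_proteome
        providers = providers_for(proteome)
        victim = variants[0].protein_id
        # a provider lacking one protein's conservation track
        partial = ResidueTrackProvider(
            "conservation",
            [a for a in proteome.annotations
             if not (a.name == "conservation" and a.protein_id == victim)],
        )
        ex = FeatureExtractor(
            proteome.proteins, scales=scales, tracks=proteome.tracks,
            providers=[partial] + providers[1:],
        ).fit(variants)
        table = ex.transform(variants)
        affected = [v.variant_id for v in variants if v.protein_id == victim]
        assert set(affected) <= set(table.excluded)
        assert not (set(affected) & set(table.data.index))

    def test_table_has_all_category_tags_and_no_missing_values(self, small_feature_table):
        table = small_feature_table
        assert set(table.categories.values()) == {"context", "content", "position", "gene"}
        assert not table.data.drop(columns="label").isna().any().any()
        assert table.segments is not None
        assert set(table.segments.columns) == {"deletion_seg", "upstream_seg", "downstream_seg"}
        # segments are strings, kept out of the numeric feature set
        assert not (set(table.segments.columns) & set(table.feature_names))
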