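"""Minimizer winnowing, the derived RY index, queries, and serialization."""

import itertools

import numpy as np
import pytest

from ryseed.ry_encoding import (
    KmerCode,
    encode_kmer,
    hash64,
    kmer_to_rycode,
    reverse_complement,
)
from ryseed.seed_index import (
    Hit,
    IndexFormatError,
    IndexParams,
    PanelSequence,
    ReferencePanel,
    build_minimizer_index,
    build_rymer_index,
    deserialize_index,
    query_minimizers,
    query_rymers,
    serialize_index,
)

from conftest import random_dna


# ---------------------------------------------------------------------------
# brute-force winnowing oracle
# ---------------------------------------------------------------------------


def oracle_minimizers(seq: str, k: int, w: int, circular: bool = False):
    """Text-level window scan: hash both orientations of every kmer, take
    per-window minima (all ties), skip kmers spanning ambiguous bases."""
    L = len(seq)
    ext = seq + seq[: k - 1] if circular else seq
    entries = []  # (hash, canon_bits, offset, is_rev) or None
    for off in range(len(ext) - k + 1):
        kmer = ext[off:off + k]
        if any(c not in "ACGT" for c in kmer):
            entries.append(None)
            continue
        f, r = encode_kmer(kmer), encode_kmer(reverse_complement(kmer))
        hf, hr = hash64(f.bits), hash64(r.bits)
        if hr < hf:
            entries.append((hr, r.bits, off, True))
        else:
            entries.append((hf, f.bits, off, False))
    n = len(entries)
    if n == 0:
        return {}
    weff = min(w, n)
    selected = set()
    for i in range(n - weff + 1):
        window = [e for e in entries[i:i + weff] if e is not None]
        if not window:
            continue
        hmin = min(e[0] for e in window)
        for e in entries[i:i + weff]:
            if e is not None and e[0] == hmin:
                selected.add(e)
    table = {}
    for _, bits, off, rev in selected:
        table.setdefault(bits, set()).add((off % L if circular else off, rev))
    return table


def _index_as_sets(idx, sid=0):
    return {
        key: {(h.offset, h.is_reverse) for h in hits if h.seq_id == sid}
        for key, hits in idx.table.items()
        if any(h.seq_id == sid for h in hits)
    }


class TestMinimizerIndex:
    @pytest.mark.parametrize("k,w,circular", [
        (3, 2, False), (3, 2, True), (5, 4, False), (7, 3, True),
        (11, 5, False), (29, 11, False),
    ])
    def test_matches_bruteforce_oracle_on_random_corpus(self, k, w, circular, rng):
        for trial in range(8):
            n = int(rng.integers(k + w, 200))
            seq = random_dna(n, rng)
            if trial % 3 == 0:  # sprinkle ambiguity
                pos = int(rng.integers(n))
                seq = seq[:pos] + "N" + seq[pos + 1:]
            panel = ReferencePanel([PanelSequence("s", seq, circular)])
            idx = build_minimizer_index(panel, IndexParams(k, w))
            assert _index_as_sets(idx) == oracle_minimizers(seq, k, w, circular)

    def test_w1_indexes_every_valid_position(self, rng):
        seq = random_dna(60, rng)
        idx = build_minimizer_index(
            ReferencePanel([PanelSequence("s", seq, False)]), IndexParams(5, 1)
        )
        covered = {h.offset for hits in idx.table.values() for h in hits}
        assert covered == set(range(len(seq) - 4))

    def test_sequence_shorter_than_k_is_empty(self):
        panel = ReferencePanel([PanelSequence("s", "ACGTA", False)])
        idx = build_minimizer_index(panel, IndexParams(6, 2))
        assert idx.table == {}

    def test_window_coverage_property(self, rng):
        """Every key is a per-window minimum for some window; no extras."""
        seq = random_dna(190, rng)
        k, w = 9, 4
        idx = build_minimizer_index(
            ReferencePanel([PanelSequence("s", seq, False)]), IndexParams(k, w)
        )
        oracle = oracle_minimizers(seq, k, w)
        assert set(idx.table) == set(oracle)

    def test_circular_equals_extended_linearization(self, rng):
        seq = random_dna(90, rng)
        k, w = 7, 3
        circ = build_minimizer_index(
            ReferencePanel([PanelSequence("s", seq, True)]), IndexParams(k, w)
        )
        lin = build_minimizer_index(
            ReferencePanel([PanelSequence("s", seq + seq[: k - 1], False)]),
            IndexParams(k, w),
        )
        lin_wrapped = {
            key: {(off % len(seq), rev) for off, rev in hits}
            for key, hits in _index_as_sets(lin).items()
        }
        assert _index_as_sets(circ) == lin_wrapped

    def test_rejects_empty_panel_and_bad_params(self):
        with pytest.raises(ValueError):
            build_minimizer_index(ReferencePanel([]), IndexParams(5, 2))
        with pytest.raises(ValueError):
            IndexParams(0, 2)
        with pytest.raises(ValueError):
            IndexParams(32, 2)
        with pytest.raises(ValueError):
            IndexParams(5, 0)

    def test_hit_cap_truncates_with_warning(self):
        panel = ReferencePanel([PanelSequence("s", "A" * 600, False)])
        with pytest.warns(UserWarning, match="cap"):
            idx = build_minimizer_index(panel, IndexParams(3, 1), max_hits=16)
        assert all(len(h) <= 16 for h in idx.table.values())


class TestRymerIndex:
    def test_every_minimizer_projects_into_the_index(self, small_panel):
        params = IndexParams(8, 3)
        minidx = build_minimizer_index(small_panel, params)
        ryidx = build_rymer_index(minidx)
        k = params.k
        assert set(ryidx.table) == {
            kmer_to_rycode(KmerCode(key, k)).bits for key in minidx.table
        }
        for ry, keys in ryidx.table.items():
            for key in keys:
                assert key in minidx.table
                assert kmer_to_rycode(KmerCode(key, k)).bits == ry
        assert len(ryidx.table) <= len(minidx.table)

    def test_transition_twins_share_one_entry(self):
        # CCC and TTT both project to YYY, so one RY entry lists both keys
        from ryseed.seed_index import MinimizerIndex

        ccc, ttt = encode_kmer("CCC"), encode_kmer("TTT")
        minidx = MinimizerIndex(
            params=IndexParams(3, 1),
            table={ccc.bits: [Hit(0, 1, False)], ttt.bits: [Hit(0, 5, False)]},
        )
        ryidx = build_rymer_index(minidx)
        assert len(ryidx.table) == 1
        (entry,) = ryidx.table.values()
        assert sorted(entry) == sorted([ccc.bits, ttt.bits])


class TestQueries:
    def test_self_query_finds_true_position(self, small_panel):
        params = IndexParams(7, 3)
        idx = build_minimizer_index(small_panel, params)
        read = small_panel[0].seq[40:40 + 7 + 3 - 1 + 20]
        found = query_minimizers(idx, read)
        assert any(
            h.seq_id == 0 and h.offset == 40 + off
            for off, _rev, _key, hits in found for h in hits
        )

    def test_all_n_read_is_empty(self, mito_indexes):
        idx, _ = mito_indexes
        assert query_minimizers(idx, "N" * 60) == []

    def test_random_read_vs_bruteforce_substring_search(self, mito_panel,
                                                        mito_indexes, rng):
        idx, _ = mito_indexes
        ref = mito_panel[0].seq
        for _ in range(10):
            read = random_dna(40, rng)
            found = query_minimizers(idx, read)
            # oracle: does any 29-mer of the read occur in the reference?
            occurs = any(
                read[i:i + 29] in ref + ref[:28]
                or str(reverse_complement(read[i:i + 29])) in ref + ref[:28]
                for i in range(len(read) - 28)
            )
            if found:
                assert occurs
            if not occurs:
                assert found == []

    def test_rescue_completeness_exhaustive(self):
        """Every transitions-only neighbor of every indexed minimizer is
        reachable through the RY path (exhaustive at k=5)."""
        rng = np.random.default_rng(7)
        seq = random_dna(60, rng)
        params = IndexParams(5, 2)
        minidx = build_minimizer_index(
            ReferencePanel([PanelSequence("s", seq, False)]), params
        )
        ryidx = build_rymer_index(minidx)
        transit = {"A": "G", "G": "A", "C": "T", "T": "C"}
        for key in minidx.table:
            kmer = "".join(
                "ACGT"[(key >> (2 * (5 - 1 - i))) & 3] for i in range(5)
            )
            for flips in itertools.product([0, 1], repeat=5):
                neighbor = "".join(
                    transit[c] if f else c for c, f in zip(kmer, flips)
                )
                matches = query_rymers(ryidx, neighbor)
                cands = {c for m in matches for c in m.candidates}
                assert key in cands, (kmer, neighbor)

    def test_transversion_neighbor_not_found(self, rng):
        seq = random_dna(60, rng)
        params = IndexParams(5, 2)
        minidx = build_minimizer_index(
            ReferencePanel([PanelSequence("s", seq, False)]), params
        )
        ryidx = build_rymer_index(minidx)
        transver = {"A": "C", "C": "A", "G": "T", "T": "G"}
        key = next(iter(minidx.table))
        kmer = "".join("ACGT"[(key >> (2 * (5 - 1 - i))) & 3] for i in range(5))
        neighbor = transver[kmer[0]] + kmer[1:]
        cands = {c for m in query_rymers(ryidx, neighbor) for c in m.candidates}
        assert key not in cands

    def test_deaminated_kmer_found_in_ry_space_only(self, mito_panel, mito_indexes):
        """A single C->T in a seed misses the kmer table but hits the RY table."""
        idx, ryidx = mito_indexes
        key = next(k for k in idx.table
                   if "C" in _decode(k, 29) and not idx.table[k][0].is_reverse)
        kmer = _decode(key, 29)
        pos = kmer.index("C")
        damaged = kmer[:pos] + "T" + kmer[pos + 1:]
        assert damaged not in (_decode(k, 29) for k in
                               (s.canon_code for s in _selections(idx, damaged)))
        cands = {c for m in query_rymers(ryidx, damaged) for c in m.candidates}
        assert key in cands


def _decode(bits, k):
    return "".join("ACGT"[(bits >> (2 * (k - 1 - i))) & 3] for i in range(k))


def _selections(idx, read):
    from ryseed.seed_index import select_read_minimizers

    return select_read_minimizers(read, idx.params)


class TestSerialization:
    def test_roundtrip_toy_pair(self, small_panel, tmp_path):
        params = IndexParams(7, 3)
        minidx = build_minimizer_index(small_panel, params)
        ryidx = build_rymer_index(minidx)
        for idx, ext in ((minidx, "mdx"), (ryidx, "rdx")):
            p = tmp_path / f"toy.{ext}"
            serialize_index(idx, str(p))
            assert deserialize_index(str(p)) == idx

    def test_roundtrip_full_scale_circular(self, mito_indexes, tmp_path):
        minidx, ryidx = mito_indexes
        p1, p2 = tmp_path / "m.mdx", tmp_path / "m.rdx"
        serialize_index(minidx, str(p1))
        serialize_index(ryidx, str(p2))
        assert deserialize_index(str(p1)) == minidx
        assert deserialize_index(str(p2)) == ryidx

    def test_byte_determinism(self, small_panel, tmp_path):
        params = IndexParams(7, 3)
        a, b = tmp_path / "a.mdx", tmp_path / "b.mdx"
        serialize_index(build_minimizer_index(small_panel, params), str(a))
        serialize_index(build_minimizer_index(small_panel, params), str(b))
        assert a.read_bytes() == b.read_bytes()

    def test_corrupted_magic_rejected(self, small_panel, tmp_path):
        p = tmp_path / "x.mdx"
        serialize_index(
            build_minimizer_index(small_panel, IndexParams(7, 3)), str(p)
        )
        raw = bytearray(p.read_bytes())
        raw[0] ^= 0xFF
        p.write_bytes(bytes(raw))
        with pytest.raises(IndexFormatError, match="magic"):
            deserialize_index(str(p))

    def test_truncation_rejected(self, small_panel, tmp_path):
        p = tmp_path / "x.mdx"
        serialize_index(
            build_minimizer_index(small_panel, IndexParams(7, 3)), str(p)
        )
        p.write_bytes(p.read_bytes()[:-5])
        with pytest.raises(IndexFormatError, match="truncated"):
            deserialize_index(str(p))
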