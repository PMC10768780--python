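"""Descriptor encoders against hand examples and independent brute-force
oracles."""

import numpy as np
import pytest

import oracles
from nmsite.config import DescriptorConfig
from nmsite.descriptors import (
    DESCRIPTOR_NAMES,
    descriptor_dims,
    encode,
    encode_all,
    encode_aslpn,
    encode_bpf,
    encode_cksnap,
    encode_dbe,
    encode_dpcp,
    encode_enac,
    encode_kmer,
    encode_mmnf,
    encode_ncp,
    encode_pseeiip,
    encode_ps2,
    encode_rckmer,
    encode_zcurve,
    load_eiip_table,
    load_property_table,
    standardize_properties,
)
from nmsite.samples import SequenceError, reverse_complement


class TestHandExamples:
    def test_bpf_identity_cases(self):
        np.testing.assert_array_equal(
            encode_bpf("ACGU"),
            [1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1],
        )
        np.testing.assert_array_equal(encode_bpf("AAAA"), [1, 0, 0, 0] * 4)

    def test_ncp_standard_table(self):
        np.testing.assert_array_equal(
            encode_ncp("ACGU"), [1, 1, 1, 0, 1, 0, 1, 0, 0, 0, 0, 1]
        )
        np.testing.assert_array_equal(encode_ncp("AA"), [1, 1, 1, 1, 1, 1])
        triplets = {tuple(encode_ncp(c)) for c in "ACGU"}
        assert len(triplets) == 4

    def test_dbe_positions(self):
        v = encode_dbe("ACG")
        expected = np.zeros(32)
        expected[1] = 1   # AC
        expected[16 + 6] = 1  # CG
        np.testing.assert_array_equal(v, expected)
        v2 = encode_dbe("AAA")
        assert v2[0] == 1 and v2[16] == 1 and v2.sum() == 2

    def test_ps2_aliases_dbe(self):
        for seq in ("ACG", "UUAGC", "ACGU" * 5):
            np.testing.assert_array_equal(encode_ps2(seq), encode_dbe(seq))

    def test_kmer_frequencies(self):
        np.testing.assert_allclose(
            encode_kmer("AACG", 1), [0.5, 0.25, 0.25, 0.0]
        )
        v = encode_kmer("AAAA", 2)
        assert v[0] == 1.0 and v.sum() == 1.0
        np.testing.assert_allclose(encode_kmer("ACGU", 1), [0.25] * 4)

    def test_rckmer_canonicalization(self):
        v = encode_rckmer("AAAA", 2)
        assert v[0] == 1.0  # class AA (rc UU)
        v2 = encode_rckmer("ACGU", 2)
        # AC (rc GU) twice out of three, CG (self) once
        assert v2[1] == pytest.approx(2 / 3)
        assert v2[6] == pytest.approx(1 / 3)

    def test_pseeiip_homopolymer(self):
        eiip = load_eiip_table()
        v = encode_pseeiip("AAA", eiip)
        assert v[0] == pytest.approx(3 * 0.1260)
        assert np.count_nonzero(v) == 1
        assert (v >= 0).all() and v.max() <= 3 * eiip.max()

    def test_cksnap_gap_blocks(self):
        v = encode_cksnap("ACGU", kmax=1)
        g0 = v[:16]
        assert g0[1] == pytest.approx(1 / 3)   # AC
        assert g0[6] == pytest.approx(1 / 3)   # CG
        assert g0[11] == pytest.approx(1 / 3)  # GU
        g1 = v[16:]
        assert g1[2] == pytest.approx(0.5)     # AG
        assert g1[7] == pytest.approx(0.5)     # CU

    def test_enac_windows(self):
        np.testing.assert_allclose(
            encode_enac("ACGU", 2),
            [0.5, 0.5, 0, 0, 0, 0.5, 0.5, 0, 0, 0, 0.5, 0.5],
        )
        v = encode_enac("ACGGU", 5)
        assert v.size == 4 and v.sum() == pytest.approx(1.0)

    def test_dpcp_single_property(self):
        table = np.zeros((16, 2))
        table[:, 0] = np.arange(16)          # varies across dinucleotides
        table[:, 1] = np.arange(16)[::-1]
        std = standardize_properties(table)
        v1 = encode_dpcp("AAA", table, variant=1)
        assert v1[0] == pytest.approx(std[0, 0])
        assert np.count_nonzero(v1) == np.count_nonzero(std[0])
        v2 = encode_dpcp("AC", table, variant=2)
        np.testing.assert_allclose(v2, std[1])

    def test_dpcp_constant_property_rejected(self):
        table = np.ones((16, 1))
        with pytest.raises(ValueError, match="constant"):
            encode_dpcp("ACGU", table, variant=2)

    def test_zcurve_homopolymer(self):
        v = encode_zcurve("A" * 9).reshape(3, 16, 3)
        for phase in range(3):
            np.testing.assert_allclose(v[phase, 0], [1.0, 1.0, 1.0])
            assert np.count_nonzero(v[phase, 1:]) == 0

    def test_zcurve_short_phase_zeros(self):
        v = encode_zcurve("ACG").reshape(3, 16, 3)
        assert np.count_nonzero(v[1]) == 0 and np.count_nonzero(v[2]) == 0

    def test_aslpn_local_frequency(self):
        v = encode_aslpn("ACA")
        np.testing.assert_allclose(v[16:], [1.0, 0.5])
        v2 = encode_aslpn("AAA")
        np.testing.assert_allclose(v2[16:], [1.0, 1.0])

    def test_mmnf_anf(self):
        v = encode_mmnf("AAGA")
        np.testing.assert_allclose(v[30:], [1.0, 1.0, 1 / 3, 3 / 4])
        homo = encode_mmnf("AAAA")
        assert homo[0] == pytest.approx(0.0)  # I(A,A) on a homopolymer
        assert encode_mmnf("GUCA")[30] == 1.0


ENCODERS = {
    "BPF": (encode_bpf, oracles.bpf, {}),
    "NCP": (encode_ncp, oracles.ncp, {}),
    "DBE": (encode_dbe, oracles.dbe, {}),
    "Kmer": (lambda s: encode_kmer(s, 3), lambda s: oracles.kmer(s, 3), {}),
    "RCKmer": (lambda s: encode_rckmer(s, 3), lambda s: oracles.rckmer(s, 3), {}),
    "CKSNAP": (lambda s: encode_cksnap(s, 2), lambda s: oracles.cksnap(s, 2), {}),
    "ENAC": (lambda s: encode_enac(s, 3), lambda s: oracles.enac(s, 3), {}),
    "Zcurve": (encode_zcurve, oracles.zcurve, {}),
    "ASLPN": (encode_aslpn, oracles.aslpn, {}),
    "MMNF": (encode_mmnf, oracles.mmnf, {}),
}


@pytest.mark.parametrize("name", sorted(ENCODERS))
def test_encoder_matches_bruteforce(name, random_sequences):
    ours, oracle, _ = ENCODERS[name]
    for seq in random_sequences:
        np.testing.assert_allclose(
            ours(seq), oracle(seq), atol=1e-12,
            err_msg=f"{name} mismatch on {seq}",
        )


def test_pseeiip_and_dpcp_match_bruteforce(random_sequences):
    eiip_arr = load_eiip_table()
    eiip = {c: eiip_arr[i] for i, c in enumerate("ACGU")}
    _, raw = load_property_table()
    std = standardize_properties(raw)
    dinucs = [a + b for a in "ACGU" for b in "ACGU"]
    table = {d: list(std[i]) for i, d in enumerate(dinucs)}
    for seq in random_sequences:
        np.testing.assert_allclose(
            encode_pseeiip(seq, eiip_arr), oracles.pseeiip(seq, eiip), atol=1e-12
        )
        for variant in (1, 2):
            np.testing.assert_allclose(
                encode_dpcp(seq, raw, variant=variant),
                oracles.dpcp(seq, table, variant), atol=1e-12,
            )


class TestInvariants:
    def test_frequency_blocks_sum_to_one(self, random_sequences):
        for seq in random_sequences[:30]:
            assert encode_kmer(seq, 2).sum() == pytest.approx(1.0, abs=1e-9)
            assert encode_rckmer(seq, 2).sum() == pytest.approx(1.0, abs=1e-9)
            ck = encode_cksnap(seq, 1).reshape(2, 16)
            np.testing.assert_allclose(ck.sum(axis=1), 1.0, atol=1e-9)
            en = encode_enac(seq, 3).reshape(-1, 4)
            np.testing.assert_allclose(en.sum(axis=1), 1.0, atol=1e-9)
            assert encode_aslpn(seq)[:16].sum() == pytest.approx(1.0, abs=1e-9)

    def test_onehot_blocks(self, random_sequences):
        for seq in random_sequences[:30]:
            bp = encode_bpf(seq).reshape(-1, 4)
            assert ((bp == 1).sum(axis=1) == 1).all()
            db = encode_dbe(seq).reshape(-1, 16)
            assert ((db == 1).sum(axis=1) == 1).all()

    def test_rckmer_revcomp_invariance(self, random_sequences):
        for seq in random_sequences[:30]:
            np.testing.assert_allclose(
                encode_rckmer(seq, 3), encode_rckmer(reverse_complement(seq), 3)
            )

    def test_determinism(self):
        seq = "ACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUA"
        a = encode_all(seq)
        b = encode_all(seq)
        for name in DESCRIPTOR_NAMES:
            np.testing.assert_array_equal(a[name].values, b[name].values)


class TestRegistry:
    def test_default_dims_on_41nt_window(self):
        cfg = DescriptorConfig()
        dims = descriptor_dims(cfg, L=41)
        expected = {
            "BPF": 164, "NCP": 123, "DBE": 640, "PS2": 640, "Kmer": 64,
            "RCKmer": 32, "PseEIIP": 64, "CKSNAP": 96, "ENAC": 148,
            "Zcurve": 144, "ASLPN": 56, "MMNF": 71,
        }
        for name, dim in expected.items():
            assert dims[name] == dim
        n_prop = len(load_property_table()[0])
        assert dims["DPCP_1"] == 16 * n_prop and dims["DPCP_2"] == n_prop

    def test_encode_all_has_14_entries_matching_registry(self):
        seq = "GC" * 20 + "A"
        out = encode_all(seq)
        assert set(out) == set(DESCRIPTOR_NAMES) and len(out) == 14
        dims = descriptor_dims(DescriptorConfig(), L=41)
        for name, vec in out.items():
            assert vec.dim == dims[name]

    def test_unknown_descriptor_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            encode("ACGU", "Kmer2")

    def test_alphabet_violation(self):
        with pytest.raises(SequenceError):
            encode_bpf("ACGN")
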