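"""Encoder correctness against naive counting oracles and fixed examples."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import umamistack as us
from umamistack._tables import (
    ALPHABET,
    APAAC_PROPERTIES,
    CTD_GROUPS,
    CTD_PROPERTIES,
    PAAC_PROPERTIES,
)
from umamistack.encoders import EncodingError

from conftest import random_peptide

# ---------------------------------------------------------------------------
# Independent brute-force oracles: naive loops over residues and pairs.
# ---------------------------------------------------------------------------


def naive_aac(seq):
    return np.array([seq.count(aa) for aa in ALPHABET]) / len(seq)


def naive_dpc(seq):
    out = []
    for a in ALPHABET:
        for b in ALPHABET:
            n = sum(
                1 for i in range(len(seq) - 1) if seq[i] == a and seq[i + 1] == b
            )
            out.append(n / (len(seq) - 1))
    return np.array(out)


def _group_of(aa, prop):
    for g, members in enumerate(CTD_GROUPS[prop]):
        if aa in members:
            return g
    raise AssertionError


def naive_ctdc(seq):
    out = []
    for prop in CTD_PROPERTIES:
        for g in range(3):
            out.append(sum(1 for aa in seq if _group_of(aa, prop) == g) / len(seq))
    return np.array(out)


def naive_ctdt(seq):
    out = []
    for prop in CTD_PROPERTIES:
        gs = [_group_of(aa, prop) for aa in seq]
        for r, s in ((0, 1), (0, 2), (1, 2)):
            n = sum(
                1
                for i in range(len(seq) - 1)
                if {gs[i], gs[i + 1]} == {r, s}
            )
            out.append(n / (len(seq) - 1))
    return np.array(out)


def naive_ctdd(seq):
    out = []
    L = len(seq)
    for prop in CTD_PROPERTIES:
        gs = [_group_of(aa, prop) for aa in seq]
        for g in range(3):
            positions = [i + 1 for i, x in enumerate(gs) if x == g]
            if not positions:
                out.extend([0.0] * 5)
                continue
            n = len(positions)
            out.append(positions[0] / L * 100)
            for q in (0.25, 0.5, 0.75, 1.0):
                out.append(positions[math.ceil(q * n) - 1] / L * 100)
    return np.array(out)


def naive_paac(seq, lam=1, omega=0.05):
    L = len(seq)
    idx = [ALPHABET.index(aa) for aa in seq]
    thetas = []
    for d in range(1, lam + 1):
        vals = []
        for i in range(L - d):
            diffs = [
                (PAAC_PROPERTIES[p][idx[i + d]] - PAAC_PROPERTIES[p][idx[i]]) ** 2
                for p in range(3)
            ]
            vals.append(sum(diffs) / 3)
        thetas.append(sum(vals) / (L - d))
    z = 1 + omega * sum(thetas)
    freqs = [seq.count(aa) / L for aa in ALPHABET]
    return np.array([f / z for f in freqs] + [omega * t / z for t in thetas])


def naive_apaac(seq, lam=1, omega=0.05):
    L = len(seq)
    idx = [ALPHABET.index(aa) for aa in seq]
    taus = []
    for d in range(1, lam + 1):
        for p in range(2):
            vals = [
                APAAC_PROPERTIES[p][idx[i]] * APAAC_PROPERTIES[p][idx[i + d]]
                for i in range(L - d)
            ]
            taus.append(sum(vals) / (L - d))
    z = 1 + omega * sum(taus)
    freqs = [seq.count(aa) / L for aa in ALPHABET]
    return np.array([f / z for f in freqs] + [omega * t / z for t in taus])


ORACLES = {
    "AAC": naive_aac,
    "DPC": naive_dpc,
    "CTDC": naive_ctdc,
    "CTDT": naive_ctdt,
    "CTDD": naive_ctdd,
    "PAAC": naive_paac,
    "APAAC": naive_apaac,
}


@pytest.mark.parametrize("scheme", us.SCHEMES)
def test_encoders_match_naive_oracle(scheme, random_peptides):
    """Vectorized encoders agree with naive loops on 100 random peptides."""
    oracle = ORACLES[scheme]
    for p in random_peptides:
        np.testing.assert_allclose(
            us.encode_peptide(p, scheme),
            oracle(p.sequence),
            rtol=0,
            atol=1e-12,
            err_msg=f"{scheme} mismatch on {p.sequence}",
        )


@given(st.text(alphabet=ALPHABET, min_size=2, max_size=30))
def test_encoder_dimensions(seq):
    p = us.Peptide("h", seq)
    for scheme, dim in us.DIMENSIONS.items():
        v = us.encode_peptide(p, scheme)
        assert v.shape == (dim,)
        assert np.isfinite(v).all()
        assert len(us.feature_names(scheme)) == dim


@given(st.text(alphabet=ALPHABET, min_size=2, max_size=30))
def test_normalization_identities(seq):
    """AAC, DPC and PAAC sum to 1; CTDC per-property triples sum to 1."""
    p = us.Peptide("h", seq)
    for scheme in ("AAC", "DPC", "PAAC"):
        assert us.encode_peptide(p, scheme).sum() == pytest.approx(1.0, abs=1e-9)
    ctdc = us.encode_peptide(p, "CTDC")
    np.testing.assert_allclose(ctdc.reshape(13, 3).sum(axis=1), 1.0, atol=1e-9)
    # composition-type blocks are non-negative
    for scheme in ("AAC", "DPC", "CTDC", "CTDD", "CTDT"):
        assert (us.encode_peptide(p, scheme) >= 0).all()


def test_order_invariance_and_sensitivity():
    """Shuffling residues preserves AAC/CTDC and generally changes the
    order-sensitive encoders."""
    rng = np.random.default_rng(5)
    changed = {s: 0 for s in ("DPC", "CTDT", "CTDD", "PAAC", "APAAC")}
    n_pep = 20
    for _ in range(n_pep):
        p = random_peptide(rng, lo=12, hi=30)
        perm = rng.permutation(len(p))
        shuffled = "".join(p.sequence[i] for i in perm)
        if shuffled == p.sequence:
            continue
        q = us.Peptide("shuf", shuffled)
        for scheme in ("AAC", "CTDC"):
            np.testing.assert_allclose(
                us.encode_peptide(p, scheme), us.encode_peptide(q, scheme), atol=1e-12
            )
        for scheme in changed:
            if not np.allclose(
                us.encode_peptide(p, scheme), us.encode_peptide(q, scheme)
            ):
                changed[scheme] += 1
    for scheme, n in changed.items():
        assert n >= n_pep // 2, f"{scheme} unexpectedly order-insensitive"


def test_homopolymer_and_fixture_examples(fixtures):
    aac = us.encode_peptide(us.Peptide("g", "GG"), "AAC")
    assert aac[ALPHABET.index("G")] == 1.0 and aac.sum() == 1.0

    aac4 = us.encode_peptide(us.Peptide("m", "ACDE"), "AAC")
    for aa in "ACDE":
        assert aac4[ALPHABET.index(aa)] == 0.25

    dpc = us.encode_peptide(us.Peptide("a", "AAA"), "DPC")
    names = us.feature_names("DPC")
    assert dpc[names.index("AA")] == 1.0 and dpc.sum() == 1.0

    # "ACAC": overlapping dipeptides AC, CA, AC
    dpc2 = us.encode_peptide(fixtures["alternating"], "DPC")
    assert dpc2[names.index("AC")] == pytest.approx(2 / 3)
    assert dpc2[names.index("CA")] == pytest.approx(1 / 3)

    # homopolymer: one group per property gets everything, no transitions
    ctdc = us.encode_peptide(fixtures["homopolymer_K"], "CTDC").reshape(13, 3)
    assert ((ctdc == 1.0).sum(axis=1) == 1).all()
    assert (us.encode_peptide(fixtures["homopolymer_K"], "CTDT") == 0).all()

    # homopolymer distribution: occurrence quantiles at 25/25/50/75/100
    ctdd = us.encode_peptide(fixtures["homopolymer_K"], "CTDD").reshape(13, 3, 5)
    for prop_block in ctdd:
        nonzero = prop_block[prop_block.sum(axis=1) > 0]
        np.testing.assert_allclose(nonzero, [[25, 25, 50, 75, 100]])

    # PAAC of a homopolymer: zero order-correlation
    paac = us.encode_peptide(fixtures["homopolymer_A"], "PAAC")
    assert paac[ALPHABET.index("A")] == 1.0 and paac[20] == 0.0

    # APAAC of a homopolymer: tau_k = omega * H_k(A)^2 / normalizer
    apaac = us.encode_peptide(fixtures["homopolymer_A"], "APAAC")
    h = APAAC_PROPERTIES[:, ALPHABET.index("A")]
    z = 1 + 0.05 * (h**2).sum()
    np.testing.assert_allclose(apaac[20:], 0.05 * h**2 / z, atol=1e-12)


def test_length_preconditions():
    one = us.Peptide("x", "A")
    for scheme in ("DPC", "CTDT"):
        with pytest.raises(EncodingError):
            us.encode_peptide(one, scheme)
    for scheme in ("PAAC", "APAAC"):
        with pytest.raises(EncodingError):
            us.encode_peptide(one, scheme)
    # lambda = 2 needs L >= 3
    with pytest.raises(EncodingError):
        us.encode_peptide(
            us.Peptide("y", "AC"), "PAAC", params=us.PseudoCompositionParams(lambda_=2)
        )
    v = us.encode_peptide(
        us.Peptide("z", "ACD"), "PAAC", params=us.PseudoCompositionParams(lambda_=2)
    )
    assert v.shape == (22,)


def test_encode_dataset_matrix_and_errors(signal_dataset):
    df = us.encode_dataset(signal_dataset, "AAC")
    assert df.shape == (len(signal_dataset), 20)
    assert list(df.index) == signal_dataset.ids
    assert df.attrs["scheme"] == "AAC"
    bad = [us.Peptide("ok", "ACDE"), us.Peptide("tiny", "A")]
    with pytest.raises(EncodingError, match="tiny"):
        us.encode_dataset(bad, "DPC")


def test_ctd_tables_partition_alphabet():
    for prop, groups in CTD_GROUPS.items():
        assert sorted("".join(groups)) == sorted(ALPHABET), prop
    # standardized property rows: zero mean, unit variance
    np.testing.assert_allclose(PAAC_PROPERTIES.mean(axis=1), 0, atol=1e-12)
    np.testing.assert_allclose(PAAC_PROPERTIES.std(axis=1), 1, atol=1e-12)
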