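"""Seven fixed-dimension peptide feature encodings.

============  ====  =====================================================
scheme        dim   description
============  ====  =====================================================
AAC             20  amino-acid composition: residue frequencies
DPC            400  dipeptide composition: ordered-pair frequencies
CTDC            39  CTD composition: group fractions, 13 properties x 3
CTDT            39  CTD transition: adjacent cross-group pair rates
CTDD           195  CTD distribution: group position quantiles (% of L)
PAAC            21  pseudo-AAC: frequencies + lambda order-correlation
APAAC           22  amphiphilic pseudo-AAC: + 2*lambda amphiphilic terms
============  ====  =====================================================

All encoders operate on validated sequences over the 20-letter alphabet
and return vectors in a fixed, documented feature order so that feature
matrices are bit-reproducible across runs.

AAC: f(i) = N(i) / L.  DPC: f(i,j) = N(i,j) / (L-1), counting the L-1
overlapping dipeptides.  CTD descriptors follow the 13-property, 3-group
convention (see :mod:`umamistack._tables`).  PAAC/APAAC follow Chou's
formulation with sequence-order rank ``lambda`` (default 1) and weight
``omega`` (default 0.05):

* PAAC: theta_d = mean over i of Theta(R_i, R_{i+d}), with Theta the mean
  squared difference of 3 standardized properties; the vector is
  [f_i / Z, ..., omega * theta_d / Z] with Z = 1 + omega * sum(theta),
  so it sums to 1.
* APAAC: tau_{2(d-1)+k} = mean over i of H_k(R_i) * H_k(R_{i+d}) for the
  two amphiphilic properties; same normalization shape (the tau block may
  be negative, so only the construction - not sum-to-one - is guaranteed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from ._tables import (
    ALPHABET,
    APAAC_PROPERTIES,
    CTD_PROPERTIES,
    PAAC_PROPERTIES,
    ctd_group_index,
)
from .io import LabeledDataset, Peptide

SCHEMES: tuple[str, ...] = ("AAC", "APAAC", "CTDC", "CTDD", "CTDT", "DPC", "PAAC")

#: Fixed output dimension per scheme.
DIMENSIONS: dict[str, int] = {
    "AAC": 20,
    "PAAC": 21,
    "APAAC": 22,
    "CTDC": 39,
    "CTDT": 39,
    "CTDD": 195,
    "DPC": 400,
}


class EncodingError(ValueError):
    """A peptide fails an encoder's length precondition."""


@dataclass(frozen=True)
class PseudoCompositionParams:
    """Sequence-order parameters for PAAC/APAAC.

    lambda_ is the maximum correlation distance (>= 1); omega weights the
    order-correlation block against the composition block.
    """

    lambda_: int = 1
    omega: float = 0.05

    def __post_init__(self) -> None:
        if self.lambda_ < 1:
            raise ValueError("lambda must be >= 1")
        if self.omega <= 0:
            raise ValueError("omega must be positive")


_DEFAULT_PSEUDO = PseudoCompositionParams()

_GROUP_INDEX = {prop: ctd_group_index(prop) for prop in CTD_PROPERTIES}
_DIPEPTIDES = ["".join(p) for p in product(ALPHABET, repeat=2)]
_DP_INDEX = {dp: i for i, dp in enumerate(_DIPEPTIDES)}
_AA_CODES = {aa: i for i, aa in enumerate(ALPHABET)}
# unordered group pairs in fixed order, matching the transition layout
_GROUP_PAIRS = ((0, 1), (0, 2), (1, 2))


def _codes(seq: str) -> np.ndarray:
    return np.fromiter((_AA_CODES[a] for a in seq), dtype=np.int64, count=len(seq))


def feature_names(scheme: str, params: PseudoCompositionParams | None = None) -> list[str]:
    """Ordered feature labels for a scheme."""
    params = params or _DEFAULT_PSEUDO
    lam = params.lambda_
    if scheme == "AAC":
        return list(ALPHABET)
    if scheme == "DPC":
        return list(_DIPEPTIDES)
    if scheme == "CTDC":
        return [f"{p}.G{g + 1}" for p in CTD_PROPERTIES for g in range(3)]
    if scheme == "CTDT":
        return [
            f"{p}.T{a + 1}{b + 1}" for p in CTD_PROPERTIES for a, b in _GROUP_PAIRS
        ]
    if scheme == "CTDD":
        return [
            f"{p}.G{g + 1}.D{q}"
            for p in CTD_PROPERTIES
            for g in range(3)
            for q in ("first", "25", "50", "75", "100")
        ]
    if scheme == "PAAC":
        return list(ALPHABET) + [f"theta{d}" for d in range(1, lam + 1)]
    if scheme == "APAAC":
        return list(ALPHABET) + [
            f"tau{d}.H{k + 1}" for d in range(1, lam + 1) for k in range(2)
        ]
    raise ValueError(f"unknown scheme {scheme!r}")


def encode_aac(p: Peptide) -> np.ndarray:
    """Amino-acid composition: 20 residue frequencies summing to 1."""
    counts = np.bincount(_codes(p.sequence), minlength=20).astype(float)
    return counts / len(p)


def encode_dpc(p: Peptide) -> np.ndarray:
    """Dipeptide composition: 400 ordered-pair frequencies over L-1 pairs."""
    L = len(p)
    if L < 2:
        raise EncodingError(f"DPC needs L >= 2, got L={L}")
    c = _codes(p.sequence)
    flat = c[:-1] * 20 + c[1:]
    counts = np.bincount(flat, minlength=400).astype(float)
    return counts / (L - 1)


def encode_ctdc(p: Peptide) -> np.ndarray:
    """CTD composition: per property, the fraction of residues per group."""
    c = _codes(p.sequence)
    out = np.empty(39)
    for i, prop in enumerate(CTD_PROPERTIES):
        groups = _GROUP_INDEX[prop][c]
        out[3 * i : 3 * i + 3] = np.bincount(groups, minlength=3) / len(p)
    return out


def encode_ctdt(p: Peptide) -> np.ndarray:
    """CTD transition: adjacent cross-group pair rates (N(r,s)+N(s,r))/(L-1)."""
    L = len(p)
    if L < 2:
        raise EncodingError(f"CTDT needs L >= 2, got L={L}")
    c = _codes(p.sequence)
    out = np.empty(39)
    for i, prop in enumerate(CTD_PROPERTIES):
        g = _GROUP_INDEX[prop][c]
        a, b = g[:-1], g[1:]
        for j, (r, s) in enumerate(_GROUP_PAIRS):
            n = np.sum((a == r) & (b == s)) + np.sum((a == s) & (b == r))
            out[3 * i + j] = n / (L - 1)
    return out


def encode_ctdd(p: Peptide) -> np.ndarray:
    """CTD distribution: positions (% of L) of the first occurrence and of
    the 25/50/75/100% quantile occurrences of each group; empty groups
    contribute five zeros. Quantile index is ceil(q * n_group), 1-based."""
    L = len(p)
    c = _codes(p.sequence)
    out = np.zeros(195)
    pos = np.arange(1, L + 1)
    k = 0
    for prop in CTD_PROPERTIES:
        g = _GROUP_INDEX[prop][c]
        for grp in range(3):
            where = pos[g == grp]
            n = where.size
            if n:
                out[k] = where[0] / L * 100.0
                for j, q in enumerate((0.25, 0.50, 0.75, 1.00), start=1):
                    out[k + j] = where[math.ceil(q * n) - 1] / L * 100.0
            k += 5
    return out


def _correlation_block(
    seq_codes: np.ndarray, lam: int, props: np.ndarray, paired: bool
) -> np.ndarray:
    """Sequence-order terms: theta_d (paired=False, averaged squared
    differences) or tau_{d,k} (paired=True, per-property products)."""
    L = seq_codes.size
    vals = props[:, seq_codes]  # (n_props, L)
    terms = []
    for d in range(1, lam + 1):
        left, right = vals[:, :-d], vals[:, d:]
        if paired:
            terms.extend(((left * right).mean(axis=1)))
        else:
            terms.append(((right - left) ** 2).mean())
    return np.asarray(terms, dtype=float)


def encode_paac(
    p: Peptide, params: PseudoCompositionParams | None = None
) -> np.ndarray:
    """Pseudo-amino-acid composition: 20 + lambda values summing to 1."""
    params = params or _DEFAULT_PSEUDO
    lam = params.lambda_
    L = len(p)
    if L < lam + 1:
        raise EncodingError(f"PAAC needs L >= lambda+1 = {lam + 1}, got L={L}")
    c = _codes(p.sequence)
    theta = _correlation_block(c, lam, PAAC_PROPERTIES, paired=False)
    freqs = np.bincount(c, minlength=20) / L
    z = 1.0 + params.omega * theta.sum()
    return np.concatenate([freqs / z, params.omega * theta / z])


def encode_apaac(
    p: Peptide, params: PseudoCompositionParams | None = None
) -> np.ndarray:
    """Amphiphilic pseudo-AAC: 20 + 2*lambda values (tau block signed)."""
    params = params or _DEFAULT_PSEUDO
    lam = params.lambda_
    L = len(p)
    if L < lam + 1:
        raise EncodingError(f"APAAC needs L >= lambda+1 = {lam + 1}, got L={L}")
    c = _codes(p.sequence)
    tau = _correlation_block(c, lam, APAAC_PROPERTIES, paired=True)
    freqs = np.bincount(c, minlength=20) / L
    z = 1.0 + params.omega * tau.sum()
    return np.concatenate([freqs / z, params.omega * tau / z])


_ENCODERS = {
    "AAC": encode_aac,
    "DPC": encode_dpc,
    "CTDC": encode_ctdc,
    "CTDT": encode_ctdt,
    "CTDD": encode_ctdd,
    "PAAC": encode_paac,
    "APAAC": encode_apaac,
}


def encode_peptide(p: Peptide, scheme: str, **kwargs) -> np.ndarray:
    """Encode one peptide under a named scheme."""
    try:
        enc = _ENCODERS[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    return enc(p, **kwargs)


def encode_dataset(
    ds: LabeledDataset | list[Peptide], scheme: str, **kwargs
) -> pd.DataFrame:
    """Encode every peptide, returning a row-parallel feature matrix.

    The DataFrame index holds peptide ids (dataset order preserved) and
    ``df.attrs["scheme"]`` records the encoding. The first failing
    peptide aborts the encoding with its id in the error message.
    """
    peptides = ds.peptides if isinstance(ds, LabeledDataset) else list(ds)
    rows = []
    for p in peptides:
        try:
            rows.append(encode_peptide(p, scheme, **kwargs))
        except EncodingError as exc:
            raise EncodingError(f"peptide {p.id!r}: {exc}") from exc
    names = feature_names(scheme, kwargs.get("params"))
    df = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, DIMENSIONS[scheme])),
        index=[p.id for p in peptides],
        columns=names,
    )
    df.attrs["scheme"] = scheme
    return df


def encode_all_schemes(
    ds: LabeledDataset | list[Peptide],
) -> dict[str, pd.DataFrame]:
    """Encode a dataset under all seven schemes (keyed by scheme name)."""
    return {scheme: encode_dataset(ds, scheme) for scheme in SCHEMES}
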